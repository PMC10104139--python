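"""Seeded generators for every input the pipeline consumes, with ground truth.

The generators emulate, at desk scale, the data the analysis was designed
for: dCache_1-like domain sequences carrying the amine (AM) or amino-acid
(AA) motif at known reference-anchored positions, thermal-shift melt curves,
one-site ITC isotherms, and domain-hit/taxonomy tables.  Every generator is
a pure function of its arguments and seed, so reruns are byte-identical and
truth tables are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .anchor_align import AMINO_ACIDS, SequenceRecord
from .architecture import FAMILY_LABELS
from .assays import Isotherm, ItcProtocol, MeltCurve, one_site_heats
from .motif import MotifModel, builtin_motif

TEMPLATE_LENGTH = 260
TEMPLATE_ID = "REF_TEMPLATE"

# Canonical residues implanted at the amine-motif positions of the template
# (PctD identities: R103, D133, W155, D173, F188, Y189, Y206, M215, S217, D235).
CANONICAL_AM = {
    103: "R", 133: "D", 155: "W", 173: "D", 188: "F",
    189: "Y", 206: "Y", 215: "M", 217: "S", 235: "D",
}


def make_reference_template(seed: int = 0, length: int = TEMPLATE_LENGTH) -> SequenceRecord:
    """Length-260 synthetic anchor sequence carrying the canonical amine-motif
    residues at their reference positions and uniform random residues elsewhere."""
    if length < max(CANONICAL_AM):
        raise ValueError(f"template length {length} too short for motif span")
    rng = np.random.default_rng(seed)
    residues = list(rng.choice(list(AMINO_ACIDS), size=length))
    for pos, res in CANONICAL_AM.items():
        residues[pos - 1] = res
    return SequenceRecord(TEMPLATE_ID, "".join(residues), "synthetic anchor")


@dataclass(frozen=True)
class SequenceSimSpec:
    """Composition and noise of a synthetic motif-scanning benchmark set."""

    n_am: int = 200
    n_aa: int = 0
    n_near_miss: int = 100
    n_random: int = 200
    mutation_rate: float = 0.05  # per non-motif site, substitutions
    indel_rate: float = 0.0  # per eligible site (outside motif guard bands)
    template_length: int = TEMPLATE_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_am, self.n_aa, self.n_near_miss, self.n_random) < 0:
            raise ValueError("counts must be >= 0")
        for rate in (self.mutation_rate, self.indel_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")


GUARD_BAND = 3  # indels forbidden within +/- this many residues of a motif site


def _out_of_class(rng: np.random.Generator, members: frozenset[str]) -> str:
    pool = sorted(set(AMINO_ACIDS) - members)
    return str(rng.choice(pool))


def _in_class(rng: np.random.Generator, members: frozenset[str]) -> str:
    return str(rng.choice(sorted(members)))


def generate_sequences(
    spec: SequenceSimSpec,
    am_motif: MotifModel | None = None,
    aa_motif: MotifModel | None = None,
) -> tuple[SequenceRecord, list[SequenceRecord], pd.DataFrame]:
    """Generate motif-implanted sequences plus an exact truth table.

    Classes: ``AM`` carries every amine-motif position within its class;
    ``AM_1mm`` additionally substitutes exactly one required position with an
    out-of-class residue (the negative-control design); ``AA`` implants the
    amino-acid motif instead; ``random`` is uniform over the 20 residues.
    Implanted classes are made exclusive: required positions of the *other*
    motif are forced out of class, so the truth table is exact.  Background
    substitutions and indels never touch the declared motif's positions
    (indels also avoid a +/-3 guard band).

    Returns (reference template, sequence records, truth table) with truth
    columns id / class / mismatch_position.
    """
    am = am_motif or builtin_motif("AM")
    aa = aa_motif or builtin_motif("AA")
    rng = np.random.default_rng(spec.seed)
    template = make_reference_template(spec.seed, spec.template_length)
    if spec.template_length < max(
        p.reference_position for m in (am, aa) for p in m.positions
    ):
        raise ValueError("template too short for motif span")

    records: list[SequenceRecord] = []
    truth_rows: list[dict] = []

    def build(klass: str, idx: int) -> None:
        own = am if klass in ("AM", "AM_1mm") else aa if klass == "AA" else None
        other = aa if klass in ("AM", "AM_1mm") else am if klass == "AA" else None
        if own is None:  # random class
            seq = list(rng.choice(list(AMINO_ACIDS), size=spec.template_length))
            mism_pos = ""
        else:
            seq = list(template.residues)
            own_positions = {p.reference_position for p in own.positions}
            # background substitutions outside the declared motif
            for i in range(spec.template_length):
                if (i + 1) not in own_positions and rng.random() < spec.mutation_rate:
                    seq[i] = str(rng.choice(list(AMINO_ACIDS)))
            # implant the declared motif (draw within class)
            for p in own.positions:
                seq[p.reference_position - 1] = _in_class(rng, p.residue_class.members)
            # exclusivity: break every required position of the other motif
            for p in other.required_positions:
                if p.reference_position not in own_positions:
                    seq[p.reference_position - 1] = _out_of_class(
                        rng, p.residue_class.members
                    )
            mism_pos = ""
            if klass == "AM_1mm":
                target = rng.choice([p.reference_position for p in own.required_positions])
                mp = next(p for p in own.positions if p.reference_position == target)
                seq[target - 1] = _out_of_class(rng, mp.residue_class.members)
                mism_pos = str(int(target))
            if spec.indel_rate > 0:
                seq = _apply_indels(seq, rng, spec.indel_rate, own_positions)
        sid = f"{klass}_{idx:05d}"
        records.append(SequenceRecord(sid, "".join(seq), f"synthetic {klass}"))
        truth_rows.append({"id": sid, "class": klass, "mismatch_position": mism_pos})

    counter = 0
    for klass, count in (
        ("AM", spec.n_am),
        ("AA", spec.n_aa),
        ("AM_1mm", spec.n_near_miss),
        ("random", spec.n_random),
    ):
        for _ in range(count):
            build(klass, counter)
            counter += 1
    truth = pd.DataFrame(truth_rows, columns=["id", "class", "mismatch_position"])
    return template, records, truth


def _apply_indels(
    seq: list[str],
    rng: np.random.Generator,
    rate: float,
    motif_positions: set[int],
) -> list[str]:
    guarded = set()
    for p in motif_positions:
        guarded.update(range(p - GUARD_BAND, p + GUARD_BAND + 1))
    out: list[str] = []
    for i, res in enumerate(seq):
        pos = i + 1
        if pos in guarded:
            out.append(res)
            continue
        r = rng.random()
        if r < rate / 2:  # deletion
            continue
        out.append(res)
        if r >= rate / 2 and r < rate:  # insertion after this site
            out.append(str(rng.choice(list(AMINO_ACIDS))))
    return out


# ---------------------------------------------------------------------------
# Melt curves

MELT_GRID_START = 23.0
MELT_GRID_END = 85.0


def generate_melt_curve(
    tm: float,
    amplitude: float = 1000.0,
    baseline_slope: float = 0.0,
    noise_sd: float = 0.0,
    width: float = 2.0,
    grid_step: float = 1.0,
    seed: int = 0,
    extra_transitions: Sequence[tuple[float, float]] = (),
    **meta,
) -> MeltCurve:
    """Sigmoidal unfolding trace over the 23-85 degC ramp.

    The transition is a falling logistic of midpoint ``tm`` and half-width
    ``width``, so the first derivative has its minimum at ``tm`` (the
    analyzer's default orientation).  ``extra_transitions`` adds further
    (midpoint, amplitude) logistics for multi-transition curves.
    """
    T = np.arange(MELT_GRID_START, MELT_GRID_END + grid_step / 2, grid_step)
    transitions = [(tm, amplitude), *extra_transitions]
    for mid, _ in transitions:
        if not (T[0] <= mid <= T[-1]):
            raise ValueError(f"transition midpoint {mid} outside the {T[0]}-{T[-1]} grid")
    F = 2000.0 + baseline_slope * (T - T[0])
    for mid, amp in transitions:
        F = F + amp / (1.0 + np.exp((T - mid) / width))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        F = F + rng.normal(0.0, noise_sd, size=T.size)
    return MeltCurve(T, F, **meta)


# ---------------------------------------------------------------------------
# ITC experiments


def generate_itc_experiment(
    n: float,
    kd_uM: float,
    dh_kcal: float,
    protocol: ItcProtocol,
    noise_sd: float = 0.0,
    blank_offset: float = 0.0,
    n_blank: int | None = None,
    seed: int = 0,
    label: str = "",
) -> Isotherm:
    """One-site isotherm with Gaussian injection noise and a constant
    dilution-heat offset, plus a matching ligand-into-buffer blank series.

    ``noise_sd`` and ``blank_offset`` are in kcal per mole of injectant.
    """
    rng = np.random.default_rng(seed)
    ideal = one_site_heats(n, kd_uM, dh_kcal, protocol)
    heats = ideal + blank_offset
    if noise_sd > 0:
        heats = heats + rng.normal(0.0, noise_sd, size=ideal.size)
    m = n_blank if n_blank is not None else protocol.n_injections
    blank = np.full(m, blank_offset)
    if noise_sd > 0:
        blank = blank + rng.normal(0.0, noise_sd, size=m)
    return Isotherm(heats, protocol, blank_heats=blank, label=label)


# ---------------------------------------------------------------------------
# Domain-hit and taxonomy tables

# One representative architecture per family (start, end, E-value exponents
# drawn at generation time).
_FAMILY_ARCHITECTURES: dict[str, list[tuple[str, int, int]]] = {
    "chemoreceptor": [("dCache_1", 30, 280), ("HAMP", 300, 352), ("MCPsignal", 370, 520)],
    "histidine_kinase": [("dCache_1", 30, 280), ("HATPase_c", 340, 440)],
    "cyclase_phosphodiesterase": [
        ("dCache_1", 30, 280), ("GGDEF", 320, 470), ("EAL", 480, 720)
    ],
    "st_phosphatase": [("dCache_1", 30, 280), ("SpoIIE", 330, 520)],
    "standalone": [("dCache_1", 30, 280)],
    "other": [("dCache_1", 30, 280), ("DUF4118", 300, 400)],
}

_PHYLA = (
    "Proteobacteria",
    "Firmicutes",
    "Bacteroidota",
    "Actinobacteriota",
    "Spirochaetota",
    "Verrucomicrobiota",
    "Halobacteriota",
)


def generate_domain_tables(
    family_mix: dict[str, float],
    n_proteins: int,
    seed: int = 0,
    hits_path: str | Path | None = None,
    taxonomy_path: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Synthetic domain-hit and GTDB-style taxonomy tables with known truth.

    ``family_mix`` maps family labels to proportions summing to 1; counts are
    apportioned deterministically (largest remainder).  Returns (hits,
    taxonomy, truth) data frames and optionally writes hit/taxonomy TSVs in
    the formats the analysis side consumes.
    """
    bad = set(family_mix) - set(FAMILY_LABELS)
    if bad:
        raise ValueError(f"unknown families in mix: {sorted(bad)}")
    total = sum(family_mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mix proportions must sum to 1 (got {total})")
    rng = np.random.default_rng(seed)
    # largest-remainder apportionment keeps the drawn mix exact
    items = sorted(family_mix.items())
    raw = [(fam, frac * n_proteins) for fam, frac in items]
    counts = {fam: int(np.floor(x)) for fam, x in raw}
    remainder = n_proteins - sum(counts.values())
    for fam, _ in sorted(raw, key=lambda t: (t[1] - np.floor(t[1]), t[0]), reverse=True)[
        :remainder
    ]:
        counts[fam] += 1

    hit_rows, tax_rows, truth_rows = [], [], []
    i = 0
    for fam, cnt in sorted(counts.items()):
        for _ in range(cnt):
            pid = f"SYN_{i:06d}.1"
            for dom, start, end in _FAMILY_ARCHITECTURES[fam]:
                evalue = 10.0 ** rng.uniform(-30, -3)
                hit_rows.append(
                    {
                        "protein_id": pid,
                        "domain": dom,
                        "start": start,
                        "end": end,
                        "evalue": evalue,
                    }
                )
            phylum = str(rng.choice(_PHYLA))
            tax_rows.append(
                {
                    "accession": pid,
                    "gtdb_taxonomy": (
                        f"d__Bacteria;p__{phylum};c__SynClass;o__SynOrder;"
                        "f__SynFamily;g__SynGenus;s__SynSpecies"
                    ),
                }
            )
            truth_rows.append({"protein_id": pid, "family": fam, "phylum": phylum})
            i += 1
    hits = pd.DataFrame(hit_rows, columns=["protein_id", "domain", "start", "end", "evalue"])
    taxonomy = pd.DataFrame(tax_rows, columns=["accession", "gtdb_taxonomy"])
    truth = pd.DataFrame(truth_rows, columns=["protein_id", "family", "phylum"])
    if hits_path is not None:
        hits.rename(columns={"domain": "domain"}).to_csv(
            hits_path, sep="\t", index=False, header=["protein_id", "domain", "start", "end", "evalue"]
        )
    if taxonomy_path is not None:
        taxonomy.to_csv(taxonomy_path, sep="\t", index=False)
    return hits, taxonomy, truth
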
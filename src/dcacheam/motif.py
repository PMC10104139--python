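"""Residue-class motif models and reference-anchored motif evaluation.

The amine-binding motif (AM_motif) is a set of residue-class constraints at
structure-defined positions of the PctD dCache_1 sensor domain; the
amino-acid-binding motif (AA_motif) is the analogous signature in PctA
numbering.  A query matches a motif when every required position, located
through a :class:`~dcacheam.anchor_align.PositionMap`, carries a residue of
the allowed class.  A query failing at exactly one required position is a
"near miss" — the predicted-non-binder negative-control category.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import yaml

from .anchor_align import (
    GAP,
    AMINO_ACIDS,
    Alignment,
    AlignParams,
    PositionMap,
    SequenceRecord,
    global_align,
    map_positions,
    write_fasta,
)

# Default residue-class memberships.  Histidine is deliberately excluded from
# POSITIVE: only R/K are reported at the charged motif sites.
CLASS_MEMBERS: dict[str, frozenset[str]] = {
    "AROMATIC": frozenset("FWY"),
    "POSITIVE": frozenset("RK"),
    "NEGATIVE": frozenset("DE"),
    "HYDROPHOBIC": frozenset("MLIVFA"),
    "SMALL_POLAR": frozenset("ST"),
    "ANY": frozenset(AMINO_ACIDS),
}


@dataclass(frozen=True)
class ResidueClass:
    """A named set of allowed residues at one motif position."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("residue class must have members")
        if not self.members <= set(AMINO_ACIDS):
            raise ValueError(f"members outside the 20 standard residues: {self.members}")
        if self.name.startswith("EXACT") and len(self.members) != 1:
            raise ValueError("EXACT class must have exactly one member")

    @staticmethod
    def named(name: str) -> "ResidueClass":
        if name.startswith("EXACT(") and name.endswith(")"):
            return ResidueClass.exact(name[6:-1])
        try:
            return ResidueClass(name, CLASS_MEMBERS[name])
        except KeyError:
            raise ValueError(
                f"unknown residue class {name!r}; known: {sorted(CLASS_MEMBERS)}"
            ) from None

    @staticmethod
    def exact(residue: str) -> "ResidueClass":
        return ResidueClass(f"EXACT({residue})", frozenset(residue))

    def matches(self, residue: str) -> bool:
        # gaps and the unknown residue 'X' never satisfy a class
        return residue in self.members

    @property
    def frequency(self) -> float:
        """Probability a uniform random residue satisfies this class."""
        return len(self.members) / 20.0


@dataclass(frozen=True)
class MotifPosition:
    reference_position: int
    residue_class: ResidueClass
    weight: Literal["required", "optional"] = "required"
    label: str = ""

    def __post_init__(self) -> None:
        if self.reference_position < 1:
            raise ValueError("reference positions are 1-based")
        if self.weight not in ("required", "optional"):
            raise ValueError("weight must be 'required' or 'optional'")

    @property
    def required(self) -> bool:
        return self.weight == "required"


@dataclass(frozen=True)
class MotifModel:
    """An ordered set of residue-class constraints on a reference numbering."""

    name: str
    reference_id: str
    positions: tuple[MotifPosition, ...]
    max_mismatch_for_match: int = 0
    near_miss_mismatches: int = 1

    def __post_init__(self) -> None:
        pos = [p.reference_position for p in self.positions]
        if pos != sorted(set(pos)):
            raise ValueError("motif positions must be strictly increasing")
        if not self.positions:
            raise ValueError("motif must have at least one position")

    @property
    def required_positions(self) -> tuple[MotifPosition, ...]:
        return tuple(p for p in self.positions if p.required)

    @property
    def reference_positions(self) -> list[int]:
        return [p.reference_position for p in self.positions]

    def random_match_probability(self) -> float:
        """Analytic full-match probability for a uniform random sequence."""
        prob = 1.0
        for p in self.required_positions:
            prob *= p.residue_class.frequency
        return prob


def _am_positions() -> tuple[MotifPosition, ...]:
    C = ResidueClass.named
    return (
        MotifPosition(103, C("POSITIVE"), "required", "R103; salt bridge above pocket"),
        MotifPosition(133, C("NEGATIVE"), "required", "D133; partner of R103"),
        MotifPosition(155, C("AROMATIC"), "required", "W155; cation-pi aromatic"),
        MotifPosition(173, C("NEGATIVE"), "required", "D173; shared with AA motif"),
        MotifPosition(188, C("AROMATIC"), "required", "F188; ligand sandwich"),
        MotifPosition(189, C("AROMATIC"), "required", "Y189; ligand sandwich"),
        MotifPosition(206, C("AROMATIC"), "optional", "Y206; cation-pi, A in McpX"),
        MotifPosition(215, C("HYDROPHOBIC"), "required", "M215; hydrophobic contact"),
        MotifPosition(217, C("SMALL_POLAR"), "required", "S217; water-mediated H-bond"),
        MotifPosition(235, ResidueClass.exact("D"), "required", "D235; terminal aspartate"),
    )


def _aa_positions() -> tuple[MotifPosition, ...]:
    # PctA numbering.  The terminal aspartate's printed PctA number is not
    # stated; 190 is this package's configurable placeholder downstream of Y144.
    C = ResidueClass.named
    return (
        MotifPosition(121, C("AROMATIC"), "required", "Y121"),
        MotifPosition(126, C("POSITIVE"), "required", "R126; binds ligand carboxylate"),
        MotifPosition(128, C("AROMATIC"), "required", "W128"),
        MotifPosition(144, C("AROMATIC"), "required", "Y144"),
        MotifPosition(190, ResidueClass.exact("D"), "required", "terminal aspartate"),
    )


def builtin_motif(name: str) -> MotifModel:
    """Return a built-in motif model: 'AM' (amine, PctD numbering) or
    'AA' (amino acid, PctA numbering)."""
    key = name.upper()
    if key == "AM":
        return MotifModel("AM", reference_id="PctD", positions=_am_positions())
    if key == "AA":
        return MotifModel("AA", reference_id="PctA", positions=_aa_positions())
    raise ValueError(f"unknown motif {name!r}; available: AM, AA")


# ---------------------------------------------------------------------------
# Motif config files (TSV or YAML)


def load_motif_config(path: str | Path, name: str = "custom", reference_id: str = "ref") -> MotifModel:
    """Load a motif from a TSV (reference_position/class/members/weight/label)
    or YAML file; explicit ``members`` override the named class's default set."""
    path = Path(path)
    if path.suffix.lower() in (".yml", ".yaml"):
        cfg = yaml.safe_load(path.read_text())
        name = cfg.get("name", name)
        reference_id = cfg.get("reference_id", reference_id)
        rows = cfg["positions"]
    else:
        rows = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                if not line.strip():
                    continue
                rows.append(dict(zip(header, line.rstrip("\n").split("\t"))))
    positions = []
    for row in rows:
        cls_name = row["class"]
        members = row.get("members") or ""
        if members:
            cls = ResidueClass(cls_name, frozenset(str(members).replace(",", "")))
        else:
            cls = ResidueClass.named(cls_name)
        positions.append(
            MotifPosition(
                int(row["reference_position"]),
                cls,
                str(row.get("weight") or "required"),
                str(row.get("label") or ""),
            )
        )
    return MotifModel(name, reference_id, tuple(positions))


# ---------------------------------------------------------------------------
# Evaluation


@dataclass(frozen=True)
class PositionRecord:
    reference_position: int
    expected_class: str
    observed: str  # residue or '-'
    matched: bool
    required: bool


@dataclass(frozen=True)
class MotifMatchResult:
    query_id: str
    motif_name: str
    records: tuple[PositionRecord, ...]
    mismatch_count: int
    label: Literal["full_match", "near_miss", "no_match"]

    @property
    def failing_positions(self) -> list[int]:
        return [r.reference_position for r in self.records if r.required and not r.matched]


def evaluate_motif(
    query_id: str, position_map: PositionMap, motif: MotifModel
) -> MotifMatchResult:
    """Evaluate one query (a row of the mapped alignment) against a motif.

    A gap at a required position counts as a mismatch, not an error; missing
    coverage of a motif position in the map is an error.
    """
    mapped = set(position_map.positions)
    missing = [p for p in motif.reference_positions if p not in mapped]
    if missing:
        raise ValueError(
            f"position map does not cover motif position(s) {missing} "
            f"of motif {motif.name!r}"
        )
    records = []
    mismatches = 0
    for mp in motif.positions:
        observed = position_map.residue(query_id, mp.reference_position)
        matched = observed != GAP and mp.residue_class.matches(observed)
        if mp.required and not matched:
            mismatches += 1
        records.append(
            PositionRecord(
                mp.reference_position, mp.residue_class.name, observed, matched, mp.required
            )
        )
    if mismatches <= motif.max_mismatch_for_match:
        label = "full_match"
    elif mismatches == motif.near_miss_mismatches:
        label = "near_miss"
    else:
        label = "no_match"
    return MotifMatchResult(query_id, motif.name, tuple(records), mismatches, label)


def detect_charged_pair_insertion(
    query_id: str,
    position_map: PositionMap,
    positive_pos: int = 103,
    negative_pos: int = 133,
) -> bool:
    """True iff the query has a positive residue at ``positive_pos`` and a
    negative one at ``negative_pos`` — the salt-bridge pair of the helical
    insertion above the amine-binding pocket.  Supporting evidence only."""
    pos_cls = ResidueClass.named("POSITIVE")
    neg_cls = ResidueClass.named("NEGATIVE")
    a = position_map.residue(query_id, positive_pos)
    b = position_map.residue(query_id, negative_pos)
    return pos_cls.matches(a) and neg_cls.matches(b)


# ---------------------------------------------------------------------------
# Collection scanning


@dataclass
class ScanTable:
    """Per-(sequence, motif) scan results plus summary counters."""

    results: list[MotifMatchResult]

    def rows(self) -> list[dict]:
        return [
            {
                "query_id": r.query_id,
                "motif": r.motif_name,
                "label": r.label,
                "mismatch_count": r.mismatch_count,
                "failing_positions": ",".join(map(str, r.failing_positions)),
            }
            for r in self.results
        ]

    def summary(self) -> dict:
        out: dict[str, dict[str, int]] = {}
        for r in self.results:
            out.setdefault(r.motif_name, {"full_match": 0, "near_miss": 0, "no_match": 0})
            out[r.motif_name][r.label] += 1
        return out

    def matches(self, motif_name: str, label: str = "full_match") -> list[str]:
        return [
            r.query_id
            for r in self.results
            if r.motif_name == motif_name and r.label == label
        ]

    def motif_names(self) -> list[str]:
        seen: list[str] = []
        for r in self.results:
            if r.motif_name not in seen:
                seen.append(r.motif_name)
        return seen

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("query_id\tmotif\tlabel\tmismatch_count\tfailing_positions\n")
            for row in self.rows():
                fh.write(
                    f"{row['query_id']}\t{row['motif']}\t{row['label']}\t"
                    f"{row['mismatch_count']}\t{row['failing_positions']}\n"
                )

    def write_summary_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2) + "\n")


def scan_collection(
    source: Alignment | Sequence[SequenceRecord],
    motifs: Sequence[MotifModel],
    reference: SequenceRecord | None = None,
    align_params: AlignParams | None = None,
) -> ScanTable:
    """Scan every sequence of an alignment (reference anchored by row) or of
    a sequence set (each query pairwise-anchored against ``reference``)
    against every motif."""
    if not motifs:
        raise ValueError("no motifs given")
    results: list[MotifMatchResult] = []
    all_positions = sorted({p for m in motifs for p in m.reference_positions})
    if isinstance(source, Alignment):
        pmap = map_positions(source, all_positions)
        query_ids = [r.id for r in source.rows if r.id != source.reference_id]
        if not query_ids:
            raise ValueError("alignment holds only the reference row")
        for qid in query_ids:
            for motif in motifs:
                results.append(evaluate_motif(qid, pmap, motif))
    else:
        seqs = list(source)
        if not seqs:
            raise ValueError("empty sequence collection")
        if reference is None:
            raise ValueError("sequence-set scanning needs a reference sequence")
        for seq in seqs:
            aln = global_align(seq, reference, align_params)
            pmap = map_positions(aln, all_positions)
            for motif in motifs:
                results.append(evaluate_motif(seq.id, pmap, motif))
    return ScanTable(results)


def extract_matches(
    table: ScanTable,
    sequences: Sequence[SequenceRecord],
    motif_name: str,
    path: str | Path,
    label: str = "full_match",
) -> int:
    """Write the sequences labelled ``label`` for ``motif_name`` to FASTA."""
    wanted = set(table.matches(motif_name, label))
    hits = [s for s in sequences if s.id in wanted]
    if hits:
        write_fasta(hits, path)
    return len(hits)


# ---------------------------------------------------------------------------
# AM vs AA comparison


def compare_motifs(
    table: ScanTable, motif_a: str = "AM", motif_b: str = "AA"
) -> dict:
    """Joint per-sequence labels over two motifs plus summary counts.

    Returns a dict with per-sequence joint labels (``'AM-only'``,
    ``'AA-only'``, ``'both'``, ``'neither'``) and the counts of each."""
    names = table.motif_names()
    if motif_a not in names or motif_b not in names:
        raise ValueError(
            f"comparison needs both motifs {motif_a!r} and {motif_b!r} in the table "
            f"(found {names})"
        )
    by_motif: dict[str, dict[str, str]] = {motif_a: {}, motif_b: {}}
    for r in table.results:
        if r.motif_name in by_motif:
            by_motif[r.motif_name][r.query_id] = r.label
    ids = sorted(set(by_motif[motif_a]) & set(by_motif[motif_b]))
    if not ids:
        raise ValueError("no sequence was scanned against both motifs")
    joint: dict[str, str] = {}
    for qid in ids:
        a_hit = by_motif[motif_a][qid] == "full_match"
        b_hit = by_motif[motif_b][qid] == "full_match"
        if a_hit and b_hit:
            joint[qid] = "both"
        elif a_hit:
            joint[qid] = f"{motif_a}-only"
        elif b_hit:
            joint[qid] = f"{motif_b}-only"
        else:
            joint[qid] = "neither"
    counts = {
        k: sum(1 for v in joint.values() if v == k)
        for k in (f"{motif_a}-only", f"{motif_b}-only", "both", "neither")
    }
    # Agreement at anchor positions constrained by both motifs: fraction of
    # scanned sequences matching both class constraints at each shared position.
    records: dict[str, dict[str, dict[int, PositionRecord]]] = {motif_a: {}, motif_b: {}}
    for r in table.results:
        if r.motif_name in records:
            records[r.motif_name][r.query_id] = {
                pr.reference_position: pr for pr in r.records
            }
    shared_positions = sorted(
        set(next(iter(records[motif_a].values()), {}))
        & set(next(iter(records[motif_b].values()), {}))
    )
    shared_agreement = {}
    for pos in shared_positions:
        agree = sum(
            1
            for qid in ids
            if records[motif_a][qid][pos].matched and records[motif_b][qid][pos].matched
        )
        shared_agreement[pos] = agree / len(ids)
    return {
        "per_sequence": joint,
        "counts": counts,
        "shared_positions": shared_positions,
        "shared_agreement": shared_agreement,
    }
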
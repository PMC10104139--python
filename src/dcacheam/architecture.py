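"""Receptor-family classification from domain architectures and phyletic summaries.

Motif-positive sensor domains occur in several receptor families that are
distinguished by the signalling (output) domains on the same protein:
MCPsignal marks chemoreceptors, HATPase_c sensor histidine kinases,
GGDEF/EAL/Guanylate_cyc/HD cyclic-(di)nucleotide turnover enzymes and SpoIIE
Ser/Thr phosphatases; a sensor domain with no output domain is stand-alone.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

FAMILY_LABELS = (
    "chemoreceptor",
    "histidine_kinase",
    "cyclase_phosphodiesterase",
    "st_phosphatase",
    "standalone",
    "other",
)

# Output-domain vocabulary, in classification priority order.
OUTPUT_DOMAIN_FAMILIES: dict[str, str] = {
    "MCPsignal": "chemoreceptor",
    "HATPase_c": "histidine_kinase",
    "GGDEF": "cyclase_phosphodiesterase",
    "EAL": "cyclase_phosphodiesterase",
    "Guanylate_cyc": "cyclase_phosphodiesterase",
    "HD": "cyclase_phosphodiesterase",
    "SpoIIE": "st_phosphatase",
}
FAMILY_PRIORITY = (
    "chemoreceptor",
    "histidine_kinase",
    "cyclase_phosphodiesterase",
    "st_phosphatase",
)

SENSOR_DOMAINS = {"dCache_1", "Cache_1", "Cache_2", "sCache"}


class DomainTableError(ValueError):
    """Raised for malformed domain-hit or taxonomy tables."""


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    domain_name: str
    start: int  # envelope, 1-based inclusive
    end: int
    evalue: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.protein_id}/{self.domain_name}: start {self.start} > end {self.end}"
            )
        if self.evalue < 0:
            raise ValueError("E-value must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap(self, other: "DomainHit") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass
class ArchitectureRecord:
    protein_id: str
    domains: list[DomainHit]  # sorted by start, non-overlapping after resolution
    family: str = ""
    multi_output: bool = False

    @property
    def domain_names(self) -> list[str]:
        return [d.domain_name for d in self.domains]


@dataclass(frozen=True)
class TaxonRecord:
    protein_id: str
    phylum: str
    lower_ranks: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.phylum:
            raise ValueError("phylum must be non-empty")


# ---------------------------------------------------------------------------
# Parsing

# hmmscan --domtblout: 22 whitespace-delimited columns then free-text
# description.  Envelope coordinates are columns 20-21 (1-based).
_DOMTBL_MIN_COLS = 23
_DOMTBL_IEVALUE_COL = 12
_DOMTBL_ENV_FROM_COL = 19
_DOMTBL_ENV_TO_COL = 20


def parse_domain_hits(
    path: str | Path,
    format: str = "tsv",
    evalue_cutoff: float = 0.01,
) -> list[DomainHit]:
    """Parse a domain-hit table, discarding hits with independent E-value
    above ``evalue_cutoff``.

    ``format`` is ``'hmmscan_domtbl'`` (HMMER3 ``--domtblout``) or ``'tsv'``
    (columns protein_id, domain, start, end, evalue; header optional).
    An empty file yields an empty list.
    """
    path = Path(path)
    if format == "hmmscan_domtbl":
        return _parse_domtbl(path, evalue_cutoff)
    if format == "tsv":
        return _parse_plain_tsv(path, evalue_cutoff)
    raise DomainTableError(f"unknown domain-table format {format!r}")


def _parse_domtbl(path: Path, cutoff: float) -> list[DomainHit]:
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < _DOMTBL_MIN_COLS:
                raise DomainTableError(
                    f"{path}:{lineno}: expected >= {_DOMTBL_MIN_COLS} columns, "
                    f"got {len(fields)}"
                )
            try:
                # hmmscan: target = domain model, query = protein
                domain = fields[0]
                protein = fields[3]
                ievalue = float(fields[_DOMTBL_IEVALUE_COL])
                start = int(fields[_DOMTBL_ENV_FROM_COL])
                end = int(fields[_DOMTBL_ENV_TO_COL])
                hit = DomainHit(protein, domain, start, end, ievalue)
            except ValueError as exc:
                raise DomainTableError(f"{path}:{lineno}: {exc}") from exc
            if hit.evalue <= cutoff:
                hits.append(hit)
    return hits


def _parse_plain_tsv(path: Path, cutoff: float) -> list[DomainHit]:
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "protein_id":  # header
                continue
            if len(fields) < 5:
                raise DomainTableError(
                    f"{path}:{lineno}: expected 5 columns, got {len(fields)}"
                )
            try:
                hit = DomainHit(
                    fields[0], fields[1], int(fields[2]), int(fields[3]), float(fields[4])
                )
            except ValueError as exc:
                raise DomainTableError(f"{path}:{lineno}: {exc}") from exc
            if hit.evalue <= cutoff:
                hits.append(hit)
    return hits


# ---------------------------------------------------------------------------
# Overlap resolution and classification


def resolve_overlaps(
    hits: Sequence[DomainHit], overlap_tolerance: float = 0.20
) -> list[DomainHit]:
    """Greedy overlap resolution for one protein's hits.

    Hits are considered in ascending E-value (ties: start, then name); a hit
    is kept iff it overlaps every already-kept hit by at most
    ``overlap_tolerance`` of the shorter hit's length.  Result sorted by start.
    """
    if not hits:
        return []
    ids = {h.protein_id for h in hits}
    if len(ids) > 1:
        raise ValueError(f"hits from multiple proteins: {sorted(ids)}")
    kept: list[DomainHit] = []
    for hit in sorted(hits, key=lambda h: (h.evalue, h.start, h.domain_name)):
        ok = True
        for other in kept:
            shorter = min(hit.length, other.length)
            if hit.overlap(other) > overlap_tolerance * shorter:
                ok = False
                break
        if ok:
            kept.append(hit)
    return sorted(kept, key=lambda h: h.start)


def classify_family(record: ArchitectureRecord) -> ArchitectureRecord:
    """Assign the receptor-family label from the resolved domain list.

    Priority when several output classes co-occur: chemoreceptor >
    histidine_kinase > cyclase_phosphodiesterase > st_phosphatase, with the
    ``multi_output`` flag set.  Sensor domain(s) only → standalone; unknown
    non-sensor domains only → other.
    """
    if not record.domains:
        raise ValueError(f"{record.protein_id}: empty domain list")
    families_present = {
        OUTPUT_DOMAIN_FAMILIES[d]
        for d in record.domain_names
        if d in OUTPUT_DOMAIN_FAMILIES
    }
    if families_present:
        for fam in FAMILY_PRIORITY:
            if fam in families_present:
                record.family = fam
                break
        record.multi_output = len(families_present) > 1
        return record
    record.multi_output = False
    if all(d in SENSOR_DOMAINS for d in record.domain_names):
        record.family = "standalone"
    else:
        record.family = "other"
    return record


def build_architectures(
    hits: Iterable[DomainHit], overlap_tolerance: float = 0.20
) -> list[ArchitectureRecord]:
    """Group hits by protein, resolve overlaps and classify each protein."""
    by_protein: dict[str, list[DomainHit]] = defaultdict(list)
    for h in hits:
        by_protein[h.protein_id].append(h)
    records = []
    for pid in sorted(by_protein):
        resolved = resolve_overlaps(by_protein[pid], overlap_tolerance)
        records.append(classify_family(ArchitectureRecord(pid, resolved)))
    return records


# ---------------------------------------------------------------------------
# Taxonomy


def read_taxonomy_tsv(path: str | Path) -> list[TaxonRecord]:
    """Read a GTDB-metadata-style TSV (accession, gtdb_taxonomy with
    ``d__...;p__...`` string) or a plain two-column (protein_id, phylum) TSV."""
    records: dict[str, TaxonRecord] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] in ("accession", "protein_id"):
                continue
            if len(fields) < 2:
                raise DomainTableError(f"{path}:{lineno}: expected >= 2 columns")
            acc, tax = fields[0], fields[1]
            if "p__" in tax:
                ranks = [t.strip() for t in tax.split(";")]
                phylum = next(
                    (r[3:] for r in ranks if r.startswith("p__")), ""
                )
                lower = tuple(r for r in ranks if not r.startswith(("d__", "p__")))
            else:
                phylum, lower = tax, ()
            if not phylum:
                raise DomainTableError(f"{path}:{lineno}: no phylum in {tax!r}")
            rec = TaxonRecord(acc, phylum, lower)
            if acc in records and records[acc].phylum != phylum:
                raise DomainTableError(
                    f"{path}:{lineno}: conflicting phylum for {acc!r}: "
                    f"{records[acc].phylum!r} vs {phylum!r}"
                )
            records[acc] = rec
    return list(records.values())


def phyletic_summary(
    records: Sequence[ArchitectureRecord], taxonomy: Sequence[TaxonRecord]
) -> pd.DataFrame:
    """Phylum × family contingency table with row/column totals.

    Proteins missing from the taxonomy are counted under ``'unassigned'``,
    never dropped; the grand total always equals ``len(records)``.
    """
    tax_map: dict[str, str] = {}
    for t in taxonomy:
        if t.protein_id in tax_map and tax_map[t.protein_id] != t.phylum:
            raise DomainTableError(
                f"conflicting taxonomy rows for {t.protein_id!r}"
            )
        tax_map[t.protein_id] = t.phylum
    counts: Counter[tuple[str, str]] = Counter()
    for rec in records:
        phylum = tax_map.get(rec.protein_id, "unassigned")
        counts[(phylum, rec.family)] += 1
    phyla = sorted({p for p, _ in counts}, key=lambda p: (p == "unassigned", p))
    table = pd.DataFrame(0, index=phyla, columns=list(FAMILY_LABELS), dtype=int)
    for (phylum, family), n in counts.items():
        table.loc[phylum, family] += n
    table["total"] = table.sum(axis=1)
    table.loc["total"] = table.sum(axis=0)
    table.index.name = "phylum"
    return table
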
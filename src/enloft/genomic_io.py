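"""Readers/writers for the external formats and the shared genomic domain types.

All coordinates inside the package are 0-based half-open (BED convention).
VCF positions are converted at this boundary and nowhere else: for a symbolic
``<DEL>`` record the deleted span ``POS..END`` (1-based) becomes
``[POS-1, END)``; for an explicit left-anchored deletion ``REF=ACGT, ALT=A``
at ``POS`` the deleted span is ``[POS-1+len(ALT), POS-1+len(REF))``.

Enhancer identifiers are canonicalized as ``chrom:start-end`` so that
JEME-style compound keys (``chr1:100-200$GENE``) load without preprocessing.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

log = logging.getLogger(__name__)

#: the four direct gene-gene interaction kinds admitted into the MegaNet
DIRECT_INTERACTION_KINDS = frozenset(
    {"protein-protein", "metabolic", "phosphorylation", "signaling"}
)

MISSING_GT = "./."


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chrom + 0-based half-open [start, end) span; the atom of overlap logic."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Base pairs shared with *other* (0 on different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        """True iff *other* lies fully inside this interval (boundaries allowed)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def distance(self, other: "GenomicInterval") -> int | None:
        """Gap between closest edges; 0 when overlapping; None across chromosomes."""
        if self.chrom != other.chrom:
            return None
        if self.overlap(other) > 0:
            return 0
        return max(self.start, other.start) - min(self.end, other.end)

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Enhancer:
    id: str
    interval: GenomicInterval
    tissues: frozenset[str] = frozenset()


@dataclass(frozen=True)
class RegulatoryEdge:
    """Directed enhancer->gene link; weight = number of tissues it is active in."""

    enhancer_id: str
    gene_id: str
    tissues: frozenset[str]

    @property
    def weight(self) -> int:
        return len(self.tissues)


@dataclass
class DeletionCall:
    interval: GenomicInterval
    genotypes: dict[str, str]
    allele_frequency: float | None
    id: str

    def hom_samples(self) -> list[str]:
        return [s for s, g in self.genotypes.items() if g == "1/1"]

    def carrier_frequency(self) -> float | None:
        """Alternate allele frequency recomputed from genotypes (None if no calls)."""
        counts = {"0/0": 0, "0/1": 1, "1/1": 2}
        called = [g for g in self.genotypes.values() if g in counts]
        if not called:
            return None
        return sum(counts[g] for g in called) / (2 * len(called))


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    indispensability: float | None = None

    def __post_init__(self) -> None:
        v = self.indispensability
        if v is not None and not (0.0 <= v <= 1.0):
            raise ValueError(f"GIS for {self.gene_id} outside [0,1]: {v}")


def parse_interval_id(text: str) -> GenomicInterval:
    """Parse the canonical ``chrom:start-end`` identifier."""
    try:
        chrom, span = text.rsplit(":", 1)
        start_s, end_s = span.split("-", 1)
        return GenomicInterval(chrom, int(start_s), int(end_s))
    except (ValueError, AttributeError) as exc:
        raise ValueError(f"malformed coordinate string {text!r}") from exc


def parse_jeme_key(key: str) -> tuple[GenomicInterval, str]:
    """Split a JEME-style ``chr:start-end$GENE`` compound key."""
    if "$" not in key:
        raise ValueError(f"not a compound enhancer$gene key: {key!r}")
    coord, gene = key.split("$", 1)
    return parse_interval_id(coord), gene


@dataclass
class NetworkTable:
    """Parsed enhancer->gene regulation table."""

    edges: list[RegulatoryEdge]
    enhancers: list[Enhancer]
    discarded_labels: Counter = field(default_factory=Counter)

    @property
    def n_discarded(self) -> int:
        return sum(self.discarded_labels.values())


def read_enhancer_network(
    path: str | Path, tissue_map: Mapping[str, str | None]
) -> NetworkTable:
    """Read a TSV of enhancer->gene regulation rows with tissue annotations.

    Accepted row shapes (comment lines start with ``#``):

    * ``enhancer<TAB>gene<TAB>tissue`` with enhancer as ``chrom:start-end``
    * ``enhancer$gene<TAB>tissue`` (JEME compound key)

    Rows whose tissue label is missing from *tissue_map* (or mapped to None)
    are dropped and counted. Edges are unique per (enhancer, gene) pair with
    the union of mapped tissue groups; enhancers are deduplicated by
    coordinates.
    """
    edge_tissues: dict[tuple[str, str], set[str]] = {}
    intervals: dict[str, GenomicInterval] = {}
    discarded: Counter = Counter()
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) == 2:
                    interval, gene = parse_jeme_key(fields[0])
                    label = fields[1]
                elif len(fields) >= 3:
                    interval = parse_interval_id(fields[0])
                    gene, label = fields[1], fields[2]
                else:
                    raise ValueError("expected 2 or 3 tab-separated fields")
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            n_rows += 1
            group = tissue_map.get(label)
            if group is None:
                discarded[label] += 1
                continue
            eid = interval.id
            intervals[eid] = interval
            edge_tissues.setdefault((eid, gene), set()).add(group)
    if n_rows == 0:
        raise ValueError(f"{path}: empty enhancer network file")
    edges = [
        RegulatoryEdge(eid, gene, frozenset(tissues))
        for (eid, gene), tissues in edge_tissues.items()
    ]
    enh_tissues: dict[str, set[str]] = {}
    for edge in edges:
        enh_tissues.setdefault(edge.enhancer_id, set()).update(edge.tissues)
    enhancers = [
        Enhancer(eid, intervals[eid], frozenset(tissues))
        for eid, tissues in enh_tissues.items()
    ]
    return NetworkTable(edges=edges, enhancers=enhancers, discarded_labels=discarded)


@dataclass
class DeletionSet:
    calls: list[DeletionCall]
    n_skipped_unresolvable: int = 0
    n_ignored_non_deletion: int = 0


def _genotype_code(gt: tuple | None, allele_index: int) -> str:
    """Normalize a pysam GT tuple against one alternate allele.

    Genotypes referencing other alternate alleles of a multi-allelic record
    count as non-carrier for this allele (conservative carrier counting).
    """
    if gt is None or any(a is None for a in gt):
        return MISSING_GT
    n_alt = sum(1 for a in gt if a == allele_index)
    return ("0/0", "0/1", "1/1")[min(n_alt, 2)]


def read_deletions(path: str | Path, pass_only: bool = False) -> DeletionSet:
    """Read deletion calls from a VCF (symbolic ``<DEL>`` or explicit alleles).

    Multi-allelic records are split into per-allele calls. Records that are
    not deletions are ignored; symbolic records whose length cannot be
    resolved (no END/SVLEN) are skipped with a warning count.
    """
    out = DeletionSet(calls=[])
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if pass_only:
                filters = list(rec.filter.keys())
                if filters and filters != ["PASS"]:
                    continue
            alts = rec.alts or ()
            for i, alt in enumerate(alts):
                allele_index = i + 1
                if alt is None:
                    continue
                if alt.startswith("<"):
                    svtype = rec.info.get("SVTYPE")
                    if alt not in ("<DEL>",) and svtype != "DEL":
                        out.n_ignored_non_deletion += 1
                        continue
                    if rec.stop > rec.start + len(rec.ref or "N"):
                        start, end = rec.start, rec.stop
                    elif "SVLEN" in rec.info:
                        svlen = rec.info["SVLEN"]
                        if isinstance(svlen, tuple):
                            svlen = svlen[min(i, len(svlen) - 1)]
                        start, end = rec.start, rec.start + abs(int(svlen))
                    else:
                        log.warning("skipping unresolvable symbolic record %s", rec.id)
                        out.n_skipped_unresolvable += 1
                        continue
                else:
                    ref = rec.ref or ""
                    if len(alt) >= len(ref) or not ref.startswith(alt):
                        out.n_ignored_non_deletion += 1
                        continue
                    start = rec.start + len(alt)
                    end = rec.start + len(ref)
                genotypes = {
                    s: _genotype_code(rec.samples[s].get("GT"), allele_index)
                    for s in samples
                }
                af = None
                if "AF" in rec.info:
                    af_val = rec.info["AF"]
                    af = float(af_val[i] if isinstance(af_val, tuple) else af_val)
                else:
                    call = DeletionCall(
                        GenomicInterval(rec.chrom, start, end), genotypes, None, ""
                    )
                    af = call.carrier_frequency()
                vid = rec.id or f"{rec.chrom}:{rec.pos}"
                if len(alts) > 1:
                    vid = f"{vid}:{allele_index}"
                out.calls.append(
                    DeletionCall(
                        interval=GenomicInterval(rec.chrom, start, end),
                        genotypes=genotypes,
                        allele_frequency=af,
                        id=vid,
                    )
                )
    return out


@dataclass(frozen=True)
class BedRecord:
    interval: GenomicInterval
    name: str | None = None


def read_bed(path: str | Path) -> list[BedRecord]:
    """Read a BED3/BED4 file of 0-based half-open intervals."""
    records: list[BedRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
            try:
                interval = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            name = fields[3] if len(fields) >= 4 else None
            records.append(BedRecord(interval, name))
    return records


def write_bed(
    path: str | Path, records: Iterable[BedRecord], header: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for rec in records:
            cols = [rec.interval.chrom, str(rec.interval.start), str(rec.interval.end)]
            if rec.name is not None:
                cols.append(rec.name)
            fh.write("\t".join(cols) + "\n")


def read_scalar_table(path: str | Path) -> dict[str, float]:
    """Read a two-column id->value TSV (e.g. GIS or per-enhancer conservation)."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            key = fields[0]
            if key in out:
                raise ValueError(f"{path}: duplicate key {key!r}")
            try:
                out[key] = float(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric value for key {key!r}") from exc
    return out


def write_scalar_table(
    path: str | Path, table: Mapping[str, float], header: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for key, value in table.items():
            fh.write(f"{key}\t{value:.6g}\n")


def read_gene_interactions(
    path: str | Path,
    allowed_types: frozenset[str] = DIRECT_INTERACTION_KINDS,
) -> tuple[list[tuple[str, str, str]], int]:
    """Read gene-gene interaction rows ``gene_a<TAB>gene_b<TAB>type``.

    Only the direct interaction kinds survive; indirect kinds (genetic,
    regulatory, ...) are excluded here so the network module can enforce a
    strict whitelist. Returns (kept rows, number excluded).
    """
    kept: list[tuple[str, str, str]] = []
    excluded = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            g1, g2, kind = fields[0], fields[1], fields[2]
            if kind not in allowed_types:
                excluded += 1
                continue
            kept.append((g1, g2, kind))
    return kept, excluded
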
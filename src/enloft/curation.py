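"""Curation of the LoF-tolerant and low-LoF-tolerance training labels.

An enhancer is LoF-tolerant when it is completely contained in a deletion
that (a) is carried homozygously by at least one healthy individual and
(b) does not touch any coding exon. A low-LoF-tolerance enhancer is one
with >50% reciprocal overlap with an ultraconserved, reporter-validated
element. The two label sets must be disjoint: on adversarial input where
an enhancer would qualify for both, it is excluded from both and logged.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .genomic_io import DeletionCall, Enhancer, GenomicInterval
from .validation import ks_compare

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LabelSet:
    """Disjoint positive/negative training labels."""

    lof_tolerant: frozenset[str]
    low_tolerance: frozenset[str]
    conflicts: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.lof_tolerant & self.low_tolerance:
            raise ValueError("label sets overlap; use LabelSet.from_calls")

    @classmethod
    def from_calls(
        cls, lof_tolerant: Iterable[str], low_tolerance: Iterable[str]
    ) -> "LabelSet":
        pos, neg = frozenset(lof_tolerant), frozenset(low_tolerance)
        both = pos & neg
        if both:
            log.warning(
                "%d enhancers qualify for both labels; excluded from both: %s",
                len(both),
                sorted(both)[:5],
            )
        return cls(pos - both, neg - both, both)


def homozygous_noncoding_deletions(
    deletions: Sequence[DeletionCall], exons: Sequence[GenomicInterval]
) -> list[DeletionCall]:
    """Keep deletions homozygous in >=1 sample and free of any exon overlap.

    Exon overlap of even a single base disqualifies a deletion (the most
    conservative reading of excluding deletions that touch coding regions).
    """
    exons_by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for exon in exons:
        exons_by_chrom[exon.chrom].append(exon)
    kept = []
    for d in deletions:
        if not d.hom_samples():
            continue
        if any(d.interval.overlap(e) > 0 for e in exons_by_chrom[d.interval.chrom]):
            continue
        kept.append(d)
    return kept


def call_lof_tolerant(
    enhancers: Sequence[Enhancer], deletions: Sequence[DeletionCall]
) -> set[str]:
    """Enhancers whose interval is 100% contained in at least one deletion.

    Partial deletions never qualify; boundary equality does. The input
    deletions are expected to be pre-filtered by
    :func:`homozygous_noncoding_deletions`.
    """
    dels_by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for d in deletions:
        dels_by_chrom[d.interval.chrom].append(d.interval)
    called = set()
    for enh in enhancers:
        if any(d.contains(enh.interval) for d in dels_by_chrom[enh.interval.chrom]):
            called.add(enh.id)
    return called


def call_low_tolerance(
    enhancers: Sequence[Enhancer],
    conserved_elements: Sequence[GenomicInterval],
    min_reciprocal: float = 0.5,
) -> set[str]:
    """Enhancers with strictly >50% reciprocal overlap with a conserved element."""
    elems_by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for c in conserved_elements:
        elems_by_chrom[c.chrom].append(c)
    called = set()
    for enh in enhancers:
        e = enh.interval
        for c in elems_by_chrom[e.chrom]:
            ov = e.overlap(c)
            if ov / e.length > min_reciprocal and ov / c.length > min_reciprocal:
                called.add(enh.id)
                break
    return called


@dataclass
class IndividualCounts:
    per_sample: dict[str, int]
    mean: float
    min: int
    max: int


def per_individual_counts(
    enhancers: Sequence[Enhancer],
    deletions: Sequence[DeletionCall],
    lof_tolerant: set[str],
) -> IndividualCounts:
    """Distinct LoF-tolerant enhancers each sample carries fully hom-deleted."""
    lof_enh = [e for e in enhancers if e.id in lof_tolerant]
    samples = sorted({s for d in deletions for s in d.genotypes})
    per_sample: dict[str, set[str]] = {s: set() for s in samples}
    for d in deletions:
        contained = [e.id for e in lof_enh if d.interval.contains(e.interval)]
        if not contained:
            continue
        for s in d.hom_samples():
            per_sample[s].update(contained)
    counts = {s: len(v) for s, v in per_sample.items()}
    values = list(counts.values()) or [0]
    return IndividualCounts(
        per_sample=counts,
        mean=sum(values) / len(values),
        min=min(values),
        max=max(values),
    )


@dataclass
class AFSummary:
    """Allele-frequency comparison of enhancer-deleting vs all deletions."""

    af_all: list[float]
    af_enhancer_deleting: list[float]
    ks_d: float | None
    ks_p: float | None
    group_afs: dict[str, list[float]] = field(default_factory=dict)
    group_comparisons: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict
    )
    skipped: list[str] = field(default_factory=list)


def allele_frequency_summary(
    deletions: Sequence[DeletionCall],
    enhancers: Sequence[Enhancer],
    grouping: Mapping[str, str] | None = None,
) -> AFSummary:
    """AF distributions of LoF-relevant (enhancer-deleting) vs all deletions.

    Per population group, group-internal allele frequencies of the
    enhancer-deleting deletions are recomputed from genotypes and compared
    pairwise between groups by two-sample KS.
    """

    def af_of(d: DeletionCall) -> float | None:
        return d.allele_frequency if d.allele_frequency is not None else d.carrier_frequency()

    af_all = [a for d in deletions if (a := af_of(d)) is not None]
    deleting = [
        d
        for d in deletions
        if any(d.interval.contains(e.interval) for e in enhancers)
    ]
    af_del = [a for d in deleting if (a := af_of(d)) is not None]
    summary = AFSummary(af_all=af_all, af_enhancer_deleting=af_del, ks_d=None, ks_p=None)
    if len(af_all) >= 2 and len(af_del) >= 2:
        ks = ks_compare(af_del, af_all)
        summary.ks_d, summary.ks_p = ks.statistic, ks.pvalue
    else:
        summary.skipped.append("overall")

    if grouping:
        groups = sorted(set(grouping.values()))
        codes = {"0/0": 0, "0/1": 1, "1/1": 2}
        for g in groups:
            members = [s for s, grp in grouping.items() if grp == g]
            afs = []
            for d in deleting:
                called = [codes[d.genotypes[s]] for s in members
                          if d.genotypes.get(s) in codes]
                if called:
                    afs.append(sum(called) / (2 * len(called)))
            summary.group_afs[g] = afs
        for i, g1 in enumerate(groups):
            for g2 in groups[i + 1:]:
                a, b = summary.group_afs[g1], summary.group_afs[g2]
                if len(a) < 2 or len(b) < 2:
                    summary.skipped.append(f"{g1} vs {g2}")
                    continue
                ks = ks_compare(a, b)
                summary.group_comparisons[(g1, g2)] = (ks.statistic, ks.pvalue)
    return summary
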
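"""Downstream statistical analyses for LoF-tolerance scores.

Tissue enrichment (Fisher's exact odds ratios), two-sample KS comparisons
of score distributions, feature group comparisons (Wilcoxon rank-sum +
Cohen's d), subsampling discovery curves, disease-enhancer matching, and
PWM-based motif enrichment with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomic_io import DeletionCall, Enhancer, GenomicInterval, RegulatoryEdge

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- KS compare

@dataclass
class KSResult:
    statistic: float
    pvalue: float
    ecdf_a: tuple[np.ndarray, np.ndarray]
    ecdf_b: tuple[np.ndarray, np.ndarray]


def _ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.sort(values)
    y = np.arange(1, len(x) + 1) / len(x)
    return x, y


def ks_compare(scores_a: Sequence[float], scores_b: Sequence[float]) -> KSResult:
    """Two-sample Kolmogorov-Smirnov D (max ECDF gap) with asymptotic p."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need >= 2 observations for a KS comparison")
    res = stats.ks_2samp(a, b, method="asymp")
    return KSResult(float(res.statistic), float(res.pvalue), _ecdf(a), _ecdf(b))


# --------------------------------------------------------- tissue enrichment

@dataclass
class EnrichmentResult:
    tissue: str
    odds_ratio: float
    p_value: float
    counts: tuple[int, int, int, int]  # a, b, c, d
    corrected: bool = False


def _odds_ratio(a: int, b: int, c: int, d: int) -> tuple[float, bool]:
    if min(a, b, c, d) == 0:
        # Haldane-Anscombe continuity correction on the ratio only
        return (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5)), True
    return (a * d) / (b * c), False


def tissue_enrichment(
    labels,
    enhancer_tissues: Mapping[str, Iterable[str]],
    label_class: str = "tolerant",
    tissues: Sequence[str] | None = None,
    counting: str = "membership",
) -> list[EnrichmentResult]:
    """Per-tissue enrichment of a label class against all other tissues.

    ``counting="membership"`` treats each (enhancer, tissue) pair as a unit,
    so an enhancer active in k tissues contributes k memberships (the
    percentage-bar view). ``counting="distinct"`` partitions enhancers into
    active-in-t vs active-elsewhere-only, the unit under which the Fisher
    null is exact when labels are assigned at random.
    """
    class_ids = (
        set(labels.lof_tolerant) if label_class == "tolerant" else set(labels.low_tolerance)
    )
    tissue_sets = {e: frozenset(t) for e, t in enhancer_tissues.items()}
    if tissues is None:
        tissues = sorted({t for ts in tissue_sets.values() for t in ts})
    results = []
    for t in tissues:
        a = b = c = d = 0
        for eid, ts in tissue_sets.items():
            in_class = eid in class_ids
            if counting == "membership":
                n_in = 1 if t in ts else 0
                n_out = len(ts) - n_in
            elif counting == "distinct":
                n_in = 1 if t in ts else 0
                n_out = 1 - n_in
            else:
                raise ValueError(f"unknown counting unit {counting!r}")
            if in_class:
                a, b = a + n_in, b + n_out
            else:
                c, d = c + n_in, d + n_out
        _, p = stats.fisher_exact([[a, b], [c, d]])
        or_, corrected = _odds_ratio(a, b, c, d)
        results.append(EnrichmentResult(t, or_, float(p), (a, b, c, d), corrected))
    return results


# --------------------------------------------------------- group comparisons

@dataclass
class GroupComparison:
    feature: str
    group_a: str
    group_b: str
    p_value: float | None
    cohens_d: float | None
    flagged: bool = False


def cohens_d(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Pooled-SD Cohen's d; positive means the first group is higher."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        return None
    pooled = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if pooled == 0:
        return None
    return float((x.mean() - y.mean()) / np.sqrt(pooled))


def rank_sum_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration for small tie-free samples, tie-corrected normal
    approximation otherwise.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(x), len(y)) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def group_comparison(matrix, labels, feature: str) -> list[GroupComparison]:
    """Compare one feature between LoF-tol, low-LoF-tol and genome-wide groups.

    Genome-wide (GW) means all enhancers carrying neither label. Returns the
    triple (LoF-tol vs GW, LoF-tol vs Low, Low vs GW).
    """
    if feature not in matrix.data.columns:
        raise KeyError(f"feature {feature!r} not in matrix")
    col = matrix.data[feature]
    pos = col.loc[col.index.isin(labels.lof_tolerant)].to_numpy()
    neg = col.loc[col.index.isin(labels.low_tolerance)].to_numpy()
    gw = col.loc[
        ~col.index.isin(labels.lof_tolerant) & ~col.index.isin(labels.low_tolerance)
    ].to_numpy()
    out = []
    for name_a, a, name_b, b in [
        ("LoF-tol", pos, "GW", gw),
        ("LoF-tol", pos, "Low-LoF-tol", neg),
        ("Low-LoF-tol", neg, "GW", gw),
    ]:
        if len(a) < 2 or len(b) < 2:
            out.append(GroupComparison(feature, name_a, name_b, None, None, True))
            continue
        d = cohens_d(a, b)
        out.append(
            GroupComparison(
                feature, name_a, name_b, rank_sum_p(a, b), d, flagged=d is None
            )
        )
    return out


# ----------------------------------------------------------- discovery curve

def discovery_curve(
    enhancers: Sequence[Enhancer],
    deletions: Sequence[DeletionCall],
    sample_ids: Sequence[str],
    step: int = 100,
    seed: int = 0,
):
    """LoF-tolerant enhancers discovered as genomes accumulate.

    Samples are shuffled once and taken in nested prefixes of *step*; the
    count of distinct fully-hom-deleted enhancers is therefore monotone
    non-decreasing. Returns a list of (n_genomes, n_discovered).
    """
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(list(sample_ids)))
    per_deletion: list[tuple[set[str], set[str]]] = []
    for d in deletions:
        contained = {e.id for e in enhancers if d.interval.contains(e.interval)}
        if contained:
            per_deletion.append((set(d.hom_samples()), contained))
    points = [(0, 0)]
    if not order:
        return points
    discovered: set[str] = set()
    sizes = list(range(step, len(order) + 1, step))
    if not sizes or sizes[-1] != len(order):
        sizes.append(len(order))
    prev = 0
    for n in sizes:
        new_samples = set(order[prev:n])
        prev = n
        for hom, contained in per_deletion:
            if hom & new_samples:
                discovered.update(contained)
        points.append((n, len(discovered)))
    return points


# ----------------------------------------------------- disease enhancer match

@dataclass(frozen=True)
class DiseaseEnhancerRecord:
    interval: GenomicInterval
    target_gene: str
    disease_type: str


@dataclass
class DiseaseMatch:
    record: DiseaseEnhancerRecord
    enhancer_id: str
    distance: int


def match_disease_enhancers(
    disease_table: Sequence[DiseaseEnhancerRecord],
    enhancers: Sequence[Enhancer],
    reg_edges: Sequence[RegulatoryEdge],
    exclude_types: Sequence[str] = ("cancer",),
) -> dict[str, list[DiseaseMatch]]:
    """Match curated disease enhancers to network enhancers by overlap.

    Overlap match first; otherwise the nearest enhancer on the same
    chromosome (edge-gap distance; ties broken by smaller start). A match
    is retained only when the reported target gene is among the matched
    enhancer's regulated genes. Disease types in *exclude_types* (e.g.
    cancer, to remove somatic-variant enhancers) are skipped.
    """
    targets: dict[str, set[str]] = {}
    for e in reg_edges:
        targets.setdefault(e.enhancer_id, set()).add(e.gene_id)
    by_chrom: dict[str, list[Enhancer]] = {}
    for enh in enhancers:
        by_chrom.setdefault(enh.interval.chrom, []).append(enh)
    excluded = {t.lower() for t in exclude_types}
    matched: dict[str, list[DiseaseMatch]] = {}
    for rec in disease_table:
        if rec.disease_type.lower() in excluded:
            continue
        candidates = by_chrom.get(rec.interval.chrom)
        if not candidates:
            log.warning("no enhancers on %s for disease record", rec.interval.chrom)
            continue
        overlapping = [e for e in candidates if e.interval.overlap(rec.interval) > 0]
        if overlapping:
            pool = overlapping
        else:
            pool = candidates
        best = min(
            pool,
            key=lambda e: (e.interval.distance(rec.interval), e.interval.start),
        )
        dist = best.interval.distance(rec.interval)
        if rec.target_gene not in targets.get(best.id, set()):
            continue
        matched.setdefault(rec.disease_type, []).append(
            DiseaseMatch(rec, best.id, int(dist))
        )
    return matched


# ------------------------------------------------------------ motif scanning

COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}
BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class PWM:
    name: str
    log_odds: np.ndarray  # shape (4, width)

    @property
    def width(self) -> int:
        return self.log_odds.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())


def pwm_from_counts(name: str, counts: np.ndarray, pseudocount: float = 0.5) -> PWM:
    """Log-odds PWM vs a uniform background from a 4 x width count matrix."""
    counts = np.asarray(counts, dtype=float)
    col_sums = counts.sum(axis=0)
    if np.any(col_sums == 0):
        raise ValueError(f"PWM {name!r} has a zero column sum")
    freq = (counts + pseudocount) / (col_sums + 4 * pseudocount)
    return PWM(name=name, log_odds=np.log2(freq / 0.25))


def load_jaspar_pwms(path, pseudocount: float = 0.5) -> list[PWM]:
    """Parse a JASPAR-style PFM text file into log-odds PWMs."""
    from Bio import motifs

    with open(path) as fh:
        parsed = motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        name = m.name or m.matrix_id
        out.append(pwm_from_counts(name, counts, pseudocount))
    return out


def _encode(seq: str) -> np.ndarray:
    return np.array([BASE_INDEX.get(b, -1) for b in seq.upper()], dtype=np.int64)


def motif_present(seq: str, pwm: PWM, threshold_fraction: float = 0.8) -> bool:
    """True iff any window on either strand scores >= the threshold.

    The threshold is a fraction of the motif's maximum achievable log-odds
    score. Windows containing N never match; sequences shorter than the
    motif are simply absent.
    """
    enc = _encode(seq)
    w = pwm.width
    if len(enc) < w:
        return False
    threshold = threshold_fraction * pwm.max_score
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return False
    wv = windows[valid]
    idx = np.arange(w)
    fwd = pwm.log_odds[wv, idx].sum(axis=1)
    if (fwd >= threshold).any():
        return True
    # reverse complement: complement bases, reverse window order
    rc = np.array([COMPLEMENT[i] for i in range(4)])[wv][:, ::-1]
    rev = pwm.log_odds[rc, idx].sum(axis=1)
    return bool((rev >= threshold).any())


@dataclass
class MotifEnrichmentRow:
    motif: str
    fraction_tolerant: float
    fraction_low: float
    fraction_gw: float
    p_tolerant_vs_gw: float
    p_low_vs_gw: float
    adj_p_tolerant_vs_gw: float = field(default=np.nan)
    adj_p_low_vs_gw: float = field(default=np.nan)


def motif_enrichment(
    sequences: Mapping[str, str],
    pwms: Sequence[PWM],
    labels,
    threshold_fraction: float = 0.8,
) -> tuple[list[MotifEnrichmentRow], dict[str, int]]:
    """Per-motif presence fractions and class-vs-GW Fisher tests (BH adjusted).

    Presence fraction = enhancers containing the motif / enhancers in the
    class. Also returns per-enhancer motif counts for the class-level
    motif-count comparison.
    """
    ids = list(sequences)
    pos = [i for i in ids if i in labels.lof_tolerant]
    neg = [i for i in ids if i in labels.low_tolerance]
    gw = [i for i in ids if i not in labels.lof_tolerant and i not in labels.low_tolerance]
    per_enh_counts = {i: 0 for i in ids}
    rows: list[MotifEnrichmentRow] = []
    for pwm in pwms:
        present = {
            i: motif_present(sequences[i], pwm, threshold_fraction) for i in ids
        }
        for i, hit in present.items():
            per_enh_counts[i] += int(hit)

        def frac(group: list[str]) -> float:
            return sum(present[i] for i in group) / len(group) if group else float("nan")

        def fisher(group: list[str]) -> float:
            a = sum(present[i] for i in group)
            b = len(group) - a
            c = sum(present[i] for i in gw)
            d = len(gw) - c
            return float(stats.fisher_exact([[a, b], [c, d]])[1])

        rows.append(
            MotifEnrichmentRow(
                motif=pwm.name,
                fraction_tolerant=frac(pos),
                fraction_low=frac(neg),
                fraction_gw=frac(gw),
                p_tolerant_vs_gw=fisher(pos),
                p_low_vs_gw=fisher(neg),
            )
        )
    adj_tol = bh_adjust([r.p_tolerant_vs_gw for r in rows])
    adj_low = bh_adjust([r.p_low_vs_gw for r in rows])
    for row, at, al in zip(rows, adj_tol, adj_low):
        row.adj_p_tolerant_vs_gw = float(at)
        row.adj_p_low_vs_gw = float(al)
    return rows, per_enh_counts


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
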
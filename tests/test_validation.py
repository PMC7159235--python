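"""Statistical validation analyses against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from enloft.curation import LabelSet
from enloft.features import FeatureMatrix
from enloft.genomic_io import DeletionCall, Enhancer, GenomicInterval, RegulatoryEdge
from enloft.validation import (
    DiseaseEnhancerRecord,
    bh_adjust,
    cohens_d,
    discovery_curve,
    ks_compare,
    match_disease_enhancers,
    motif_present,
    motif_enrichment,
    pwm_from_counts,
    tissue_enrichment,
    group_comparison,
)


def brute_force_ks_d(a, b):
    """O(n^2) scan: max ECDF gap over every pooled point."""
    a, b = np.asarray(a), np.asarray(b)
    best = 0.0
    for x in np.concatenate([a, b]):
        gap = abs(np.mean(a <= x) - np.mean(b <= x))
        best = max(best, gap)
    return best


class TestKSCompare:
    def test_identical_samples(self):
        x = [0.1, 0.2, 0.3, 0.4]
        assert ks_compare(x, x).statistic == pytest.approx(0.0)

    def test_disjoint_support(self):
        a = [0.01, 0.05, 0.09]
        b = [0.91, 0.95, 0.99]
        assert ks_compare(a, b).statistic == pytest.approx(1.0)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0, 1, size=100)
        b = rng.normal(0.5, 1.2, size=100)
        res = ks_compare(a, b)
        assert res.statistic == pytest.approx(brute_force_ks_d(a, b), abs=1e-12)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_compare([0.5], [0.1, 0.2])


def hypergeom_fisher_p(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    p_obs = stats.hypergeom.pmf(a, n, row1, col1)
    total = 0.0
    for k in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        pk = stats.hypergeom.pmf(k, n, row1, col1)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return total


class TestTissueEnrichment:
    def make_inputs(self, tables):
        """tables: tissue -> (a, b, c, d) membership counts, one tissue pair."""
        # two tissues T and O; counts realised through explicit memberships
        a, b, c, d = tables
        enh_tissues = {}
        labels_pos = []
        idx = 0
        for _ in range(a):
            enh_tissues[f"P{idx}"] = {"T"}
            labels_pos.append(f"P{idx}")
            idx += 1
        for _ in range(b):
            enh_tissues[f"P{idx}"] = {"O"}
            labels_pos.append(f"P{idx}")
            idx += 1
        for _ in range(c):
            enh_tissues[f"U{idx}"] = {"T"}
            idx += 1
        for _ in range(d):
            enh_tissues[f"U{idx}"] = {"O"}
            idx += 1
        labels = LabelSet.from_calls(labels_pos, [])
        return labels, enh_tissues

    def test_balanced_table_no_association(self):
        labels, enh_tissues = self.make_inputs((10, 10, 10, 10))
        res = {r.tissue: r for r in tissue_enrichment(labels, enh_tissues)}
        assert res["T"].odds_ratio == pytest.approx(1.0)
        assert res["T"].p_value == pytest.approx(1.0)

    def test_or_sixteen_matches_hypergeometric_enumeration(self):
        labels, enh_tissues = self.make_inputs((8, 2, 2, 8))
        res = {r.tissue: r for r in tissue_enrichment(labels, enh_tissues)}
        assert res["T"].odds_ratio == pytest.approx(16.0)
        assert res["T"].p_value == pytest.approx(
            hypergeom_fisher_p(8, 2, 2, 8), rel=1e-9
        )

    def test_zero_cell_corrected_and_flagged(self):
        labels, enh_tissues = self.make_inputs((0, 10, 10, 10))
        res = {r.tissue: r for r in tissue_enrichment(labels, enh_tissues)}
        assert res["T"].corrected
        assert res["T"].odds_ratio < 1.0

    def test_membership_counting_unit(self):
        """An enhancer active in k tissues contributes k memberships."""
        labels = LabelSet.from_calls(["P0"], [])
        enh_tissues = {"P0": {"T", "O", "X"}, "U0": {"O"}}
        res = {r.tissue: r for r in tissue_enrichment(labels, enh_tissues)}
        assert res["T"].counts == (1, 2, 0, 1)


class TestGroupComparison:
    def make_matrix(self, pos, neg, gw):
        vals = np.concatenate([pos, neg, gw])
        ids = (
            [f"P{i}" for i in range(len(pos))]
            + [f"N{i}" for i in range(len(neg))]
            + [f"G{i}" for i in range(len(gw))]
        )
        m = FeatureMatrix(data=pd.DataFrame({"f": vals}, index=ids))
        labels = LabelSet.from_calls(
            [f"P{i}" for i in range(len(pos))], [f"N{i}" for i in range(len(neg))]
        )
        return m, labels

    def test_identical_groups_d_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        m, labels = self.make_matrix(x, x, x)
        comps = group_comparison(m, labels, "f")
        assert all(c.cohens_d == pytest.approx(0.0) for c in comps)

    def test_unit_shift_gives_d_near_one(self):
        rng = np.random.default_rng(21)
        pos = rng.normal(1.0, 1.0, size=500)
        gw = rng.normal(0.0, 1.0, size=500)
        m, labels = self.make_matrix(pos, rng.normal(1.0, 1.0, 5), gw)
        comp = group_comparison(m, labels, "f")[0]  # LoF-tol vs GW
        assert comp.cohens_d == pytest.approx(1.0, abs=0.15)
        assert comp.p_value < 1e-10

    def test_constant_feature_flagged(self):
        x = np.ones(10)
        m, labels = self.make_matrix(x, x, x)
        comps = group_comparison(m, labels, "f")
        assert all(c.flagged for c in comps)

    def test_small_group_skipped(self):
        m, labels = self.make_matrix(np.array([1.0, 2.0]), np.array([1.0]),
                                     np.array([1.0, 2.0, 3.0]))
        comps = group_comparison(m, labels, "f")
        assert comps[1].flagged and comps[1].p_value is None

    def test_sign_convention(self):
        assert cohens_d([2.0, 3.0, 4.0], [0.0, 1.0, 2.0]) > 0


class TestBHAdjust:
    def test_printed_triple(self):
        # manual step-up: 0.01*3/1, 0.02*3/2, 0.03*3/3 -> all 0.03
        adj = bh_adjust([0.01, 0.02, 0.03])
        assert adj == pytest.approx([0.03, 0.03, 0.03])

    def test_single_and_equal(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert bh_adjust([0.1, 0.1, 0.1]) == pytest.approx([0.1, 0.1, 0.1])

    def test_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_range_validation(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestDiscoveryCurve:
    def make_world(self, n_samples=20, seed=0):
        rng = np.random.default_rng(seed)
        enhancers = [
            Enhancer(f"chr1:{i * 100 + 20}-{i * 100 + 70}",
                     GenomicInterval("chr1", i * 100 + 20, i * 100 + 70))
            for i in range(30)
        ]
        samples = [f"S{i}" for i in range(n_samples)]
        dels = []
        for i, e in enumerate(enhancers):
            carriers = rng.choice(samples, size=rng.integers(1, 4), replace=False)
            gts = {s: ("1/1" if s in carriers else "0/0") for s in samples}
            dels.append(DeletionCall(
                GenomicInterval("chr1", e.interval.start - 10, e.interval.end + 10),
                gts, None, f"D{i}",
            ))
        return enhancers, dels, samples

    def test_monotone_and_endpoints(self):
        enhancers, dels, samples = self.make_world()
        curve = discovery_curve(enhancers, dels, samples, step=5, seed=1)
        counts = [c for _, c in curve]
        assert curve[0] == (0, 0)
        assert all(b >= a for a, b in zip(counts, counts[1:]))
        assert curve[-1][1] == 30  # all samples discover the full set

    def test_no_samples(self):
        enhancers, dels, _ = self.make_world()
        assert discovery_curve(enhancers, dels, [], step=5) == [(0, 0)]


class TestDiseaseMatching:
    def setup_world(self):
        enhancers = [
            Enhancer("chr1:100-200", GenomicInterval("chr1", 100, 200)),
            Enhancer("chr1:400-500", GenomicInterval("chr1", 400, 500)),
        ]
        edges = [
            RegulatoryEdge("chr1:100-200", "G1", frozenset({"A"})),
            RegulatoryEdge("chr1:400-500", "G2", frozenset({"A"})),
        ]
        return enhancers, edges

    def test_overlap_with_matching_target(self):
        enhancers, edges = self.setup_world()
        rec = DiseaseEnhancerRecord(GenomicInterval("chr1", 150, 250), "G1", "skin")
        out = match_disease_enhancers([rec], enhancers, edges)
        assert out["skin"][0].enhancer_id == "chr1:100-200"

    def test_target_mismatch_dropped(self):
        enhancers, edges = self.setup_world()
        rec = DiseaseEnhancerRecord(GenomicInterval("chr1", 150, 250), "G9", "skin")
        assert match_disease_enhancers([rec], enhancers, edges) == {}

    def test_equidistant_tie_prefers_smaller_start(self):
        enhancers, edges = self.setup_world()
        # gaps to chr1:100-200 and chr1:400-500 are both 99
        rec = DiseaseEnhancerRecord(GenomicInterval("chr1", 299, 301), "G1", "skin")
        out = match_disease_enhancers([rec], enhancers, edges)
        assert out["skin"][0].enhancer_id == "chr1:100-200"

    def test_cancer_rows_excluded(self):
        enhancers, edges = self.setup_world()
        rec = DiseaseEnhancerRecord(GenomicInterval("chr1", 150, 250), "G1", "cancer")
        assert match_disease_enhancers([rec], enhancers, edges) == {}


def brute_force_presence(seq, pwm, frac=0.8):
    """Exhaustive window scoring on both strands."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    thr = frac * pwm.max_score
    for strand_seq in (seq, "".join(comp.get(b, "N") for b in reversed(seq))):
        for i in range(len(strand_seq) - pwm.width + 1):
            window = strand_seq[i : i + pwm.width]
            if any(b not in idx for b in window):
                continue
            score = sum(pwm.log_odds[idx[b], j] for j, b in enumerate(window))
            if score >= thr:
                return True
    return False


class TestMotifScanning:
    @pytest.fixture()
    def pwm(self):
        consensus = "TTATGCAAAT"
        counts = np.array(
            [[91 if c == b else 3 for c in consensus] for b in "ACGT"], float
        )
        return pwm_from_counts("POUX", counts)

    def test_exact_consensus_present(self, pwm):
        assert motif_present("CG" * 10 + "TTATGCAAAT" + "AC" * 10, pwm)

    def test_reverse_complement_detected(self, pwm):
        rc = "ATTTGCATAA"
        assert motif_present("GG" * 8 + rc + "CC" * 8, pwm)

    def test_all_n_and_short_sequences_absent(self, pwm):
        assert not motif_present("N" * 50, pwm)
        assert not motif_present("TTATG", pwm)

    def test_matches_brute_force_on_fixture(self, pwm):
        rng = np.random.default_rng(31)
        bases = np.array(list("ACGT"))
        seqs = ["".join(bases[rng.integers(0, 4, size=60)]) for _ in range(8)]
        seqs += ["AA" + "TTATGCAAAT" + "GG", "N" * 30]
        for s in seqs:
            assert motif_present(s, pwm) == brute_force_presence(s, pwm)

    def test_zero_column_rejected(self):
        with pytest.raises(ValueError):
            pwm_from_counts("bad", np.zeros((4, 5)))

    def test_enrichment_fractions_and_bh(self, pwm):
        labels = LabelSet.from_calls(["a", "b"], ["c"])
        seqs = {
            "a": "AC" * 30, "b": "AC" * 30,
            "c": "GG" + "TTATGCAAAT" + "CC" * 20,
            "d": "AC" * 30, "e": "TT" + "TTATGCAAAT" + "AA" * 20,
        }
        rows, counts = motif_enrichment(seqs, [pwm], labels)
        row = rows[0]
        assert row.fraction_tolerant == 0.0
        assert row.fraction_low == 1.0
        assert row.fraction_gw == 0.5
        assert counts["c"] == 1 and counts["a"] == 0
        assert 0 <= row.adj_p_low_vs_gw <= 1
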
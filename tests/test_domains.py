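"""Domain classification, hyper calls, pileups and exact statistics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pmdkit.domains import (
    assign_genes_to_domains,
    call_hypermethylated,
    classify_pmds,
    decile_analysis,
    fisher_exact,
    pileup_matrix,
    spearman,
    wilcoxon_rank_sum,
)
from pmdkit.genome import GenomeLayout, GenomicInterval
from pmdkit.segmentation import Domain
from pmdkit.tracks import BinnedTrack


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


def track(values, bin_size=10_000):
    layout = GenomeLayout(("chr1",), (len(values) * bin_size,))
    return BinnedTrack.from_layout(layout, bin_size, np.asarray(values, dtype=float))


def fisher_two_sided_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration with exact binomials."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


class TestClassifyPmds:
    @staticmethod
    def _planted(seed):
        # 20 PMDs: first 10 high-K9/low-K27, rest the reverse
        rng = np.random.default_rng(3)
        n = 20
        k9 = np.where(np.arange(n) < 10, 3.0, 1.0) + rng.normal(0, 0.1, n)
        k27 = np.where(np.arange(n) < 10, 1.0, 3.0) + rng.normal(0, 0.1, n)
        layout = GenomeLayout(("chr1",), (n * 100_000,))
        pmds = [
            Domain(iv("chr1", i * 100_000, (i + 1) * 100_000), "PMD") for i in range(n)
        ]
        k9_t = BinnedTrack.from_layout(layout, 100_000, k9)
        k27_t = BinnedTrack.from_layout(layout, 100_000, k27)
        return pmds, k9_t, k27_t

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_separated_classes_fully_recovered(self, seed):
        pmds, k9_t, k27_t = self._planted(seed)
        cl = classify_pmds(pmds, k9_t, k27_t, seed=seed)
        assert cl.labels[:10] == ["K9-marked"] * 10
        assert cl.labels[10:] == ["K27-marked"] * 10

    def test_six_points_match_bruteforce_min_ss(self):
        feats = np.array(
            [[0.5, 2.0], [0.7, 2.2], [0.4, 1.8], [2.5, 0.3], [2.8, 0.6], [2.2, 0.4]]
        )
        layout = GenomeLayout(("chr1",), (600_000,))
        pmds = [Domain(iv("chr1", i * 100_000, (i + 1) * 100_000), "PMD") for i in range(6)]
        k9_t = BinnedTrack.from_layout(layout, 100_000, feats[:, 0])
        k27_t = BinnedTrack.from_layout(layout, 100_000, feats[:, 1])
        cl = classify_pmds(pmds, k9_t, k27_t, seed=0)
        # brute force min within-cluster SS over all 2-partitions (z-scored feats)
        z = (feats - feats.mean(0)) / feats.std(0)
        best, best_ss = None, np.inf
        for assign in itertools.product((0, 1), repeat=6):
            assign = np.array(assign)
            if assign.min() == assign.max():
                continue
            ss = sum(
                ((z[assign == g] - z[assign == g].mean(0)) ** 2).sum() for g in (0, 1)
            )
            if ss < best_ss:
                best_ss, best = ss, assign
        got = np.array([l == "K9-marked" for l in cl.labels])
        assert np.array_equal(got, best.astype(bool)) or np.array_equal(
            got, ~best.astype(bool)
        )

    def test_swapped_mark_order_flips_labels_consistently(self):
        pmds, k9_t, k27_t = self._planted(0)
        cl = classify_pmds(pmds, k9_t, k27_t, seed=0)
        swapped = classify_pmds(pmds, k27_t, k9_t, seed=0)
        # labelling keys on the first (K9) track's centroid: swapping marks
        # swaps which PMDs are 'K9-marked', but the partition is identical
        assert [l == "K9-marked" for l in cl.labels] == [
            l == "K27-marked" for l in swapped.labels
        ]

    def test_too_few_pmds_rejected(self):
        pmds, k9_t, k27_t = self._planted(0)
        with pytest.raises(ValueError):
            classify_pmds(pmds[:1], k9_t, k27_t)


class TestCallHypermethylated:
    def test_inclusive_boundary(self):
        out = call_hypermethylated([60.0], [65.0])
        assert bool(out["hyper"][0]) and out["delta"][0] == pytest.approx(5.0)

    def test_just_below_threshold(self):
        out = call_hypermethylated([60.0], [64.9])
        assert not bool(out["hyper"][0])

    def test_missing_domain_excluded(self):
        out = call_hypermethylated([60.0, np.nan], [70.0, 70.0])
        assert len(out) == 1

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=20))
    @settings(derandomize=True, max_examples=40)
    def test_monotone_in_threshold(self, deltas):
        wt = np.full(len(deltas), 50.0)
        ko = 50.0 + np.array(deltas)
        low = call_hypermethylated(wt, ko, threshold_pp=3.0)["hyper"].sum()
        high = call_hypermethylated(wt, ko, threshold_pp=7.0)["hyper"].sum()
        assert high <= low


class TestPileupMatrix:
    def test_constant_track_fills_matrix(self):
        t = track(np.full(400, 7.0))
        domains = [iv("chr1", 1_200_000, 2_200_000)]
        pm = pileup_matrix(domains, t)
        assert np.allclose(pm.matrix[0], 7.0)

    def test_default_column_count(self):
        t = track(np.full(400, 1.0))
        pm = pileup_matrix([iv("chr1", 1_000_000, 2_000_000)], t)
        assert pm.matrix.shape[1] == 300

    def test_step_track_profile(self):
        vals = np.full(400, 10.0)
        vals[120:220] = 2.0  # low inside domain 1.2-2.2 Mb
        t = track(vals)
        pm = pileup_matrix([iv("chr1", 1_200_000, 2_200_000)], t)
        cols = pm.column_means()
        assert np.allclose(cols[100:200], 2.0)  # body
        assert np.allclose(cols[:100], 10.0) and np.allclose(cols[200:], 10.0)

    def test_rank_order_is_permutation(self):
        t = track(np.arange(400, dtype=float))
        domains = [
            iv("chr1", 100_000, 400_000),
            iv("chr1", 1_000_000, 1_400_000),
            iv("chr1", 2_000_000, 2_500_000),
        ]
        pm = pileup_matrix(domains, t, rank_key=[1.0, 3.0, 2.0])
        assert len(pm.domains) == 3
        assert {d.start for d in pm.domains} == {100_000, 1_000_000, 2_000_000}
        assert pm.rank_key.tolist() == [3.0, 2.0, 1.0]

    def test_flank_beyond_chromosome_is_nan(self):
        t = track(np.full(400, 1.0))
        pm = pileup_matrix([iv("chr1", 0, 1_000_000)], t)
        assert np.isnan(pm.matrix[0, :100]).all()

    def test_subbin_domain_uses_domain_mean(self):
        t = track(np.full(400, 3.0))
        pm = pileup_matrix([iv("chr1", 1_000_000, 1_005_000)], t)
        assert np.allclose(pm.matrix[0, 100:200], 3.0)


class TestDecileAnalysis:
    def test_ten_distinct_windows_one_per_decile(self):
        v = track(np.arange(10, dtype=float), 1000)
        c = track(np.arange(10, dtype=float)[::-1].copy(), 1000)
        summary, rho, _ = decile_analysis(v, c)
        assert summary["n"].tolist() == [1] * 10
        assert rho == pytest.approx(-1.0)

    def test_value_equal_covariate_rho_one(self):
        vals = np.random.default_rng(1).normal(size=100)
        summary, rho, _ = decile_analysis(track(vals, 1000), track(vals.copy(), 1000))
        assert rho == pytest.approx(1.0)

    def test_independent_value_rho_near_zero(self):
        rng = np.random.default_rng(123)
        v = track(rng.normal(size=1000), 1000)
        c = track(rng.normal(size=1000), 1000)
        _, rho, _ = decile_analysis(v, c)
        assert abs(rho) < 0.08

    def test_constant_covariate_rejected(self):
        v = track(np.arange(20, dtype=float), 1000)
        c = track(np.full(20, 1.0), 1000)
        with pytest.raises(ValueError, match="constant"):
            decile_analysis(v, c)


class TestFisherExact:
    def test_balanced_table_p_one(self):
        _, p = fisher_exact([[5, 5], [5, 5]])
        assert p == 1.0

    def test_zero_margin_warns_p_one(self):
        with pytest.warns(UserWarning, match="zero margin"):
            _, p = fisher_exact([[0, 0], [3, 4]])
        assert p == 1.0

    def test_matches_enumeration_oracle_small_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            cells = rng.integers(0, 11, 4)
            if cells.sum() == 0 or (cells[:2].sum() == 0 or cells[2:].sum() == 0):
                continue
            a, b, c, d = (int(x) for x in cells)
            if (a + c) == 0 or (b + d) == 0:
                continue
            _, p = fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), rel=1e-9)


class TestWilcoxonRankSum:
    def test_identical_multisets_p_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 2.0], [2.0, 1.0, 2.0])
        assert p == 1.0

    def test_small_sample_exact(self):
        # 20 equally likely rank assignments; both extremes -> p = 2/20
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_shifted_normals_strongly_significant(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 200)
        b = rng.normal(1, 1, 200)
        _, p = wilcoxon_rank_sum(a, b)
        assert p < 1e-10

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestSpearman:
    def test_perfect_agreement(self):
        a = [1.0, 5.0, 3.0, 4.0]
        assert spearman(a, a)[0] == pytest.approx(1.0)

    def test_perfect_reversal(self):
        a = np.array([1.0, 5.0, 3.0, 4.0, 2.0])
        assert spearman(a, -a)[0] == pytest.approx(-1.0)

    def test_hand_computed_five_pairs(self):
        # ranks d = (−1, 1, −1, 1, 0): rho = 1 − 6*4 / (5*24) = 0.8
        rho, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestGeneAssignment:
    DOMAINS = [iv("chr1", 0, 1000), iv("chr1", 1000, 2000)]

    def test_contained_gene_assigned(self):
        assert assign_genes_to_domains([iv("chr1", 100, 300)], self.DOMAINS) == [0]

    def test_straddling_gene_unassigned(self):
        assert assign_genes_to_domains([iv("chr1", 900, 1100)], self.DOMAINS) == [None]

    def test_random_genes_match_containment_oracle(self):
        rng = np.random.default_rng(9)
        genes = [
            iv("chr1", int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 1900, 50), rng.integers(1, 300, 50))
        ]
        got = assign_genes_to_domains(genes, self.DOMAINS)
        for g, hit in zip(genes, got):
            expect = None
            for i, d in enumerate(self.DOMAINS):
                if d.start <= g.start and g.end <= d.end:
                    expect = i
                    break
            assert hit == expect
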
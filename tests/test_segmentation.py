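"""HMM fitting/decoding and domain calling against brute-force oracles."""

import itertools

import numpy as np
import pytest

from pmdkit.genome import ExclusionSet, GenomeLayout, GenomicInterval
from pmdkit.segmentation import (
    HmmParams,
    call_chromatin_domains,
    call_pmds,
    fit_two_state_hmm,
    viterbi_decode,
)
from pmdkit.tracks import BinnedTrack, CpGRecord


def track_from_values(values, bin_size=10_000):
    layout = GenomeLayout(("chr1",), (len(values) * bin_size,))
    return BinnedTrack.from_layout(layout, bin_size, np.asarray(values, dtype=float))


def path_logprob(values, path, params):
    """Joint log probability of a state path; NaN emits nothing."""
    lp = np.log(params.startprob[path[0]])
    for t in range(1, len(path)):
        lp += np.log(params.transmat[path[t - 1], path[t]])
    for t, s in enumerate(path):
        if not np.isnan(values[t]):
            lp += -0.5 * (
                np.log(2 * np.pi * params.variances[s])
                + (values[t] - params.means[s]) ** 2 / params.variances[s]
            )
    return lp


def brute_force_viterbi(values, params):
    """Exhaustive enumeration of all 2^T paths; NaN emits nothing."""
    best_path, best_lp = None, -np.inf
    for path in itertools.product((0, 1), repeat=len(values)):
        lp = path_logprob(values, path, params)
        if lp > best_lp:
            best_lp, best_path = lp, path
    return np.array(best_path)


def random_params(rng):
    means = np.sort(rng.uniform(0, 100, 2))
    if means[1] - means[0] < 1:
        means[1] += 1
    p, q = rng.uniform(0.05, 0.95, 2)
    return HmmParams(
        means=means,
        variances=rng.uniform(1, 100, 2),
        transmat=np.array([[p, 1 - p], [1 - q, q]]),
        startprob=np.array([0.5, 0.5]),
    )


class TestFit:
    def test_recovers_well_separated_means(self):
        rng = np.random.default_rng(2)
        states = np.repeat([0, 1, 0, 1, 0, 1], 80)
        vals = np.where(states == 0, rng.normal(30, 5, len(states)),
                        rng.normal(80, 5, len(states)))
        params = fit_two_state_hmm(track_from_values(vals), seed=0)
        assert abs(params.means[0] - 30) < 2
        assert abs(params.means[1] - 80) < 2

    def test_constant_track_degenerate(self):
        params = fit_two_state_hmm(track_from_values(np.full(200, 7.0)))
        assert params.degenerate

    def test_loglikelihood_nondecreasing(self):
        rng = np.random.default_rng(4)
        vals = np.concatenate([rng.normal(30, 8, 150), rng.normal(70, 8, 150)])
        params = fit_two_state_hmm(track_from_values(vals), seed=0)
        ll = np.array(params.log_likelihoods)
        assert np.all(np.diff(ll) >= -1e-8)

    def test_state_zero_is_lower_mean(self):
        rng = np.random.default_rng(9)
        vals = np.concatenate([rng.normal(80, 5, 100), rng.normal(20, 5, 100)])
        params = fit_two_state_hmm(track_from_values(vals), seed=0)
        assert params.means[0] < params.means[1]


class TestViterbi:
    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            T = int(rng.integers(1, 13))
            params = random_params(rng)
            vals = rng.uniform(0, 100, T)
            vals[rng.random(T) < 0.2] = np.nan
            got = viterbi_decode(track_from_values(vals), params)
            expect = brute_force_viterbi(vals, params)
            # probability-equal paths (exact ties) are equally valid optima
            assert path_logprob(vals, got, params) == pytest.approx(
                path_logprob(vals, expect, params), abs=1e-9
            )

    def test_dominant_emission_limit_is_nearest_mean(self):
        params = HmmParams(
            means=np.array([20.0, 80.0]),
            variances=np.array([1.0, 1.0]),
            transmat=np.array([[0.5, 0.5], [0.5, 0.5]]),
            startprob=np.array([0.5, 0.5]),
        )
        vals = np.array([10.0, 90.0, 25.0, 75.0, 19.0])
        got = viterbi_decode(track_from_values(vals), params)
        assert np.array_equal(got, [0, 1, 0, 1, 0])

    def test_diagonal_transitions_hold_single_state(self):
        params = HmmParams(
            means=np.array([40.0, 60.0]),
            variances=np.array([400.0, 400.0]),
            transmat=np.array([[0.9999, 0.0001], [0.0001, 0.9999]]),
            startprob=np.array([0.9, 0.1]),
        )
        vals = np.array([50.0] * 20)  # uninformative emissions
        got = viterbi_decode(track_from_values(vals), params)
        assert len(set(got.tolist())) == 1


def _cpgs_for_profile(profile, spacing=500):
    """One CpG every `spacing` bp with deterministic 20-read calls; profile
    maps position -> methylation fraction."""
    records = []
    for pos in range(0, profile.size * spacing, spacing):
        frac = profile[pos // spacing]
        records.append(CpGRecord("chr1", pos, int(round(frac * 20)), 20))
    return records


class TestCallPmds:
    LAYOUT = GenomeLayout(("chr1",), (10_000_000,))

    def test_flat_methylome_gives_single_hmd(self):
        profile = np.full(20_000, 0.8)
        records = _cpgs_for_profile(profile)
        pmds, hmds = call_pmds(records, self.LAYOUT, seed=0)
        assert pmds == []
        assert len(hmds) == 1
        assert hmds[0].interval.length == 10_000_000

    def test_planted_domain_recovered_within_two_windows(self):
        profile = np.full(20_000, 0.85)
        profile[8000:12000] = 0.5  # 2 Mb low domain at 4-6 Mb
        records = _cpgs_for_profile(profile)
        pmds, _ = call_pmds(records, self.LAYOUT, seed=0)
        assert len(pmds) == 1
        assert abs(pmds[0].interval.start - 4_000_000) <= 20_000
        assert abs(pmds[0].interval.end - 6_000_000) <= 20_000

    def test_short_low_domain_filtered(self):
        profile = np.full(20_000, 0.85)
        profile[8000:8300] = 0.4  # 150 kb: below the 200 kb minimum
        records = _cpgs_for_profile(profile)
        pmds, _ = call_pmds(records, self.LAYOUT, seed=0)
        assert pmds == []

    def test_pmds_start_and_end_on_cpgs(self, sim_config, methylome_wt, called_domains):
        records, truth = methylome_wt
        pmds, _ = called_domains
        cpg_pos = {(r.chrom, r.pos) for r in records}
        for d in pmds:
            assert (d.interval.chrom, d.interval.start) in cpg_pos
            assert (d.interval.chrom, d.interval.end - 1) in cpg_pos

    def test_pmd_hmd_partition(self, sim_config, methylome_wt, called_domains):
        _, truth = methylome_wt
        pmds, hmds = called_domains
        ivs = sorted(
            [d.interval for d in pmds + hmds] + list(truth.exclusions.intervals),
            key=lambda v: (sim_config.layout.order(v.chrom), v.start),
        )
        for a, b in zip(ivs, ivs[1:]):
            if a.chrom == b.chrom:
                assert a.end <= b.start, "domains overlap"
                # any uncovered gap is a dropped sub-minimum-length remnant
                assert b.start - a.end < 200_000


class TestChromatinDomains:
    def test_enriched_blocks_recovered(self):
        rng = np.random.default_rng(6)
        layout = GenomeLayout(("chr1",), (25_000 * 2000,))
        states = np.zeros(2000, dtype=int)
        for s in range(100, 2000, 400):
            states[s : s + 120] = 1
        vals = rng.normal(np.where(states == 1, 3.0, 1.0), 0.3)
        track = BinnedTrack.from_layout(layout, 25_000, vals)
        domains = call_chromatin_domains(track, seed=0)
        truth = [
            GenomicInterval("chr1", s * 25_000, (s + 120) * 25_000)
            for s in range(100, 2000, 400)
        ]
        from pmdkit.genome import jaccard

        assert jaccard([d.interval for d in domains], truth) >= 0.9

    def test_flat_ratio_degenerate_no_domains(self):
        layout = GenomeLayout(("chr1",), (25_000 * 200,))
        track = BinnedTrack.from_layout(layout, 25_000, np.ones(200))
        assert call_chromatin_domains(track) == []

    def test_seed_invariant_after_relabelling(self):
        rng = np.random.default_rng(8)
        layout = GenomeLayout(("chr1",), (25_000 * 600,))
        states = (np.arange(600) // 150) % 2
        vals = rng.normal(np.where(states == 1, 2.5, 1.0), 0.3)
        track = BinnedTrack.from_layout(layout, 25_000, vals)
        d1 = call_chromatin_domains(track, seed=1)
        d2 = call_chromatin_domains(track, seed=42)
        assert [d.interval for d in d1] == [d.interval for d in d2]
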
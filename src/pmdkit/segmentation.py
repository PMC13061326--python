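"""Two-state HMM segmentation of methylation and chromatin tracks.

PMDs and HMDs are called from 10 kb window-mean methylation with a two-state
Gaussian HMM (Baum-Welch fit, Viterbi decode) followed by domain-level
post-processing: trim each low-methylation run to its first/last CpG, bridge
runs separated by less than twice the window size, take the complement as
HMDs, excise exclusion regions, drop domains shorter than a minimum length
and merge bookended same-kind neighbours. Chromatin (H3K9me3 / H3K27me3)
domains reuse the same HMM on 25 kb IP/input ratio windows without the
PMD-specific post-processing.

Missing windows never split a domain: both fitting and decoding treat a NaN
window as emission-free, propagating state through transitions only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .genome import (
    ExclusionSet,
    GenomeLayout,
    GenomicInterval,
    merge_intervals,
    subtract_intervals,
)
from .tracks import BinnedTrack, CpGRecord, methylation_track

log = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class HmmParams:
    """Two-state Gaussian HMM parameters; state 0 is the lower-mean state."""

    means: np.ndarray
    variances: np.ndarray
    transmat: np.ndarray
    startprob: np.ndarray
    degenerate: bool = False
    log_likelihoods: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.startprob = np.asarray(self.startprob, dtype=float)
        if not self.degenerate:
            if np.any(self.variances <= 0):
                raise ValueError("variances must be positive")
            if not np.allclose(self.transmat.sum(axis=1), 1.0):
                raise ValueError("transition rows must sum to 1")


@dataclass
class Domain:
    interval: GenomicInterval
    kind: str
    n_windows: int = 0
    mean_value: float = float("nan")

    @property
    def length(self) -> int:
        return self.interval.length


def _log_emission(values: np.ndarray, params: HmmParams) -> np.ndarray:
    """(T, 2) log emission density; NaN observations contribute 0 (both states)."""
    T = len(values)
    out = np.zeros((T, 2))
    obs = ~np.isnan(values)
    for s in range(2):
        out[obs, s] = -0.5 * (
            _LOG2PI
            + np.log(params.variances[s])
            + (values[obs] - params.means[s]) ** 2 / params.variances[s]
        )
    return out


def _sequences(track: BinnedTrack) -> list[np.ndarray]:
    return [track.values[sl] for sl in track.chrom_slices().values()]


def _forward_backward(values: np.ndarray, params: HmmParams):
    """Scaled forward-backward. Returns (loglik, gamma, xi_sum)."""
    logB = _log_emission(values, params)
    B = np.exp(logB - logB.max(axis=1, keepdims=True))
    Bscale = logB.max(axis=1)
    A = params.transmat
    T = len(values)
    alpha = np.zeros((T, 2))
    beta = np.zeros((T, 2))
    c = np.zeros(T)
    alpha[0] = params.startprob * B[0]
    c[0] = alpha[0].sum()
    alpha[0] /= c[0]
    for t in range(1, T):
        alpha[t] = (alpha[t - 1] @ A) * B[t]
        c[t] = alpha[t].sum()
        alpha[t] /= c[t]
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi_sum = np.zeros((2, 2))
    for t in range(T - 1):
        xi = (alpha[t][:, None] * A) * (B[t + 1] * beta[t + 1])[None, :] / c[t + 1]
        xi_sum += xi
    loglik = float(np.log(c).sum() + Bscale.sum())
    return loglik, gamma, xi_sum


def fit_two_state_hmm(
    track: BinnedTrack,
    max_iter: int = 200,
    tol: float = 1e-4,
    seed: int = 0,
) -> HmmParams:
    """Baum-Welch fit of a two-state Gaussian HMM on a binned track.

    Chromosomes are independent sequences sharing parameters. Emission means
    are initialised by k-means (k=2) on the observed window values and the
    transition matrix at 0.99 on the diagonal; iteration stops when the
    relative log-likelihood gain falls below `tol`. State 0 is relabelled to
    the lower-mean state before returning. A track whose observed values are
    all identical yields a flagged degenerate single-state result.
    """
    obs = track.values[~np.isnan(track.values)]
    if len(obs) < 2 or np.ptp(obs) == 0:
        m = float(obs[0]) if len(obs) else float("nan")
        return HmmParams(
            means=np.array([m, m]),
            variances=np.array([0.0, 0.0]),
            transmat=np.eye(2),
            startprob=np.array([1.0, 0.0]),
            degenerate=True,
        )
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(obs.reshape(-1, 1))
    means = np.sort(km.cluster_centers_.ravel())
    var0 = max(obs.var() / 4.0, 1e-6)
    params = HmmParams(
        means=means,
        variances=np.array([var0, var0]),
        transmat=np.array([[0.99, 0.01], [0.01, 0.99]]),
        startprob=np.array([0.5, 0.5]),
    )
    seqs = [s for s in _sequences(track) if len(s)]
    prev_ll = -np.inf
    for _ in range(max_iter):
        ll = 0.0
        g_obs_sum = np.zeros(2)
        mean_num = np.zeros(2)
        var_num = np.zeros(2)
        xi_tot = np.zeros((2, 2))
        start_tot = np.zeros(2)
        gammas = []
        for vals in seqs:
            l, gamma, xi = _forward_backward(vals, params)
            ll += l
            gammas.append(gamma)
            xi_tot += xi
            start_tot += gamma[0]
            obs_mask = ~np.isnan(vals)
            g_obs_sum += gamma[obs_mask].sum(axis=0)
            mean_num += gamma[obs_mask].T @ vals[obs_mask]
        new_means = mean_num / g_obs_sum
        for vals, gamma in zip(seqs, gammas):
            obs_mask = ~np.isnan(vals)
            diff = vals[obs_mask, None] - new_means[None, :]
            var_num += (gamma[obs_mask] * diff**2).sum(axis=0)
        params.means = new_means
        params.variances = np.maximum(var_num / g_obs_sum, 1e-8)
        denom = xi_tot.sum(axis=1, keepdims=True)
        params.transmat = np.where(denom > 0, xi_tot / denom, params.transmat)
        params.startprob = start_tot / start_tot.sum()
        params.log_likelihoods.append(ll)
        if prev_ll > -np.inf and (ll - prev_ll) <= tol * abs(prev_ll):
            break
        prev_ll = ll
    if params.means[0] > params.means[1]:  # relabel: state 0 = lower mean
        params.means = params.means[::-1].copy()
        params.variances = params.variances[::-1].copy()
        params.startprob = params.startprob[::-1].copy()
        params.transmat = params.transmat[::-1, ::-1].copy()
    return params


def viterbi_decode(track: BinnedTrack, params: HmmParams) -> np.ndarray:
    """Most probable joint state path per window (0 = lower-mean state).

    Decoding runs per chromosome; NaN windows carry no emission term and are
    bridged purely by the transition structure.
    """
    if params.degenerate:
        return np.zeros(len(track.values), dtype=int)
    out = np.empty(len(track.values), dtype=int)
    logA = np.log(params.transmat + 1e-300)
    logpi = np.log(params.startprob + 1e-300)
    for sl in track.chrom_slices().values():
        vals = track.values[sl]
        T = len(vals)
        if T == 0:
            continue
        logB = _log_emission(vals, params)
        delta = np.zeros((T, 2))
        psi = np.zeros((T, 2), dtype=int)
        delta[0] = logpi + logB[0]
        for t in range(1, T):
            cand = delta[t - 1][:, None] + logA
            psi[t] = cand.argmax(axis=0)
            delta[t] = cand.max(axis=0) + logB[t]
        path = np.empty(T, dtype=int)
        path[-1] = delta[-1].argmax()
        for t in range(T - 2, -1, -1):
            path[t] = psi[t + 1][path[t + 1]]
        out[sl] = path
    return out


def _state_runs(track: BinnedTrack, states: np.ndarray, state: int):
    """Maximal runs of `state` as intervals spanning window boundaries."""
    runs = []
    for sl in track.chrom_slices().values():
        sub = states[sl.start : sl.stop]
        wins = track.windows[sl.start : sl.stop]
        i = 0
        while i < len(sub):
            if sub[i] == state:
                j = i
                while j < len(sub) and sub[j] == state:
                    j += 1
                runs.append(
                    GenomicInterval(wins[i].chrom, wins[i].start, wins[j - 1].end)
                )
                i = j
            else:
                i += 1
    return runs


def _trim_to_cpgs(
    intervals: Sequence[GenomicInterval], records: Sequence[CpGRecord]
) -> list[GenomicInterval]:
    """Shrink each interval to [first CpG, last CpG + 1]; drop CpG-free ones."""
    pos_by_chrom: dict[str, np.ndarray] = {}
    for r in records:
        pos_by_chrom.setdefault(r.chrom, [])
    for r in records:
        pos_by_chrom[r.chrom].append(r.pos)  # type: ignore[union-attr]
    pos_by_chrom = {c: np.asarray(p) for c, p in pos_by_chrom.items()}
    out = []
    for iv in intervals:
        pos = pos_by_chrom.get(iv.chrom)
        if pos is None:
            continue
        lo = np.searchsorted(pos, iv.start, side="left")
        hi = np.searchsorted(pos, iv.end, side="left")
        if hi > lo:
            out.append(GenomicInterval(iv.chrom, int(pos[lo]), int(pos[hi - 1]) + 1))
    return out


def _annotate(
    intervals: Sequence[GenomicInterval], kind: str, track: BinnedTrack
) -> list[Domain]:
    from .tracks import interval_means

    means = interval_means(track, intervals)
    out = []
    for iv, m in zip(intervals, means):
        n = max(1, int(round(iv.length / track.bin_size)))
        out.append(Domain(iv, kind, n_windows=n, mean_value=float(m)))
    return out


def call_pmds(
    meth_cpgs: Sequence[CpGRecord],
    layout: GenomeLayout,
    exclusions: Optional[ExclusionSet] = None,
    window: int = 10_000,
    min_length: int = 200_000,
    min_coverage: int = 1,
    seed: int = 0,
) -> tuple[list[Domain], list[Domain]]:
    """Segment a CpG methylome into PMDs and HMDs.

    Pipeline: window-mean methylation -> two-state Gaussian HMM -> Viterbi ->
    low-state runs as raw PMDs -> trim each to its first/last CpG -> bridge
    PMDs whose gap is < 2*window -> complement within chromosomes as HMDs ->
    subtract exclusion regions from both -> drop domains < min_length ->
    merge bookended same-kind neighbours. Returns (pmds, hmds); the two sets
    are disjoint and, together with exclusions and sub-min_length remnants,
    tile the chromosomes.
    """
    exclusions = exclusions or ExclusionSet.empty()
    covered = {r.chrom for r in meth_cpgs}
    skipped = [c for c in layout.chrom_names if c not in covered]
    if skipped:
        log.warning("no CpGs on chromosome(s) %s: skipped", ",".join(skipped))
    track = methylation_track(meth_cpgs, layout, window, min_coverage)
    params = fit_two_state_hmm(track, seed=seed)
    if params.degenerate:
        raw_pmds: list[GenomicInterval] = []
    else:
        states = viterbi_decode(track, params)
        raw_pmds = _state_runs(track, states, state=0)
    pmds = _trim_to_cpgs(raw_pmds, meth_cpgs)
    pmds = merge_intervals(pmds, max_gap=2 * window - 1, layout=layout)
    hmds: list[GenomicInterval] = []
    for chrom in layout.chrom_names:
        if chrom in skipped:
            continue
        whole = [GenomicInterval(chrom, 0, layout.size(chrom))]
        hmds.extend(subtract_intervals(whole, [p for p in pmds if p.chrom == chrom]))
    pmds = subtract_intervals(pmds, exclusions.intervals, layout)
    hmds = subtract_intervals(hmds, exclusions.intervals, layout)
    n_small = sum(1 for iv in pmds + hmds if iv.length < min_length)
    if n_small:
        log.info("dropping %d domains shorter than %d bp", n_small, min_length)
    pmds = merge_intervals([iv for iv in pmds if iv.length >= min_length], 0, layout)
    hmds = merge_intervals([iv for iv in hmds if iv.length >= min_length], 0, layout)
    return _annotate(pmds, "PMD", track), _annotate(hmds, "HMD", track)


def call_chromatin_domains(
    ratio_track: BinnedTrack,
    exclusions: Optional[ExclusionSet] = None,
    kind: str = "K9-domain",
    seed: int = 0,
) -> list[Domain]:
    """Call high-signal chromatin domains from a 25 kb IP/input ratio track.

    The high-ratio HMM state's runs become domains; exclusion regions are
    subtracted. No bridging or length filter is applied.
    """
    exclusions = exclusions or ExclusionSet.empty()
    params = fit_two_state_hmm(ratio_track, seed=seed)
    if params.degenerate:
        log.warning("degenerate track: no chromatin domains called")
        return []
    states = viterbi_decode(ratio_track, params)
    runs = _state_runs(ratio_track, states, state=1)
    runs = subtract_intervals(runs, exclusions.intervals)
    return _annotate(runs, kind, ratio_track)
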
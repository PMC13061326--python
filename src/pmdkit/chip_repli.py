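"""ChIP-seq input normalization and repli-seq replication timing.

ChIP windows are scaled to counts per 10 million mapped reads with a 0.5
pseudocount and divided by the equivalently scaled input; windows with zero
coverage in every sample are masked. Replication timing is the per-window
log2 early/late ratio of RPM-scaled repli-seq fraction counts, quantile
normalized across replicates, loess-smoothed per chromosome and averaged.
Higher smoothed values mean earlier replication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .tracks import BinnedTrack

log = logging.getLogger(__name__)


@dataclass
class NormalizedChip:
    track: BinnedTrack
    ip_total: float
    input_total: float
    offset: float = 0.5


@dataclass
class ReplicationTiming:
    smoothed: BinnedTrack
    raw_ratios: list[BinnedTrack]
    meta: dict = field(default_factory=dict)


def normalize_chip(
    ip: BinnedTrack,
    input_: BinnedTrack,
    ip_total: float,
    input_total: float,
    offset: float = 0.5,
) -> NormalizedChip:
    """IP/input enrichment per window on the counts-per-10M scale.

    value = ((ip + offset) * 1e7 / ip_total) / ((input + offset) * 1e7 / input_total).
    The pseudocount keeps zero-input windows finite; windows with zero reads
    in both samples (or missing in either) are masked out.
    """
    if not ip.same_grid(input_):
        raise ValueError("IP and input tracks are on different window grids")
    if ip_total <= 0 or input_total <= 0:
        raise ValueError("library totals must be positive")
    ipv, inv = ip.values, input_.values
    ratio = ((ipv + offset) * 1e7 / ip_total) / ((inv + offset) * 1e7 / input_total)
    dead = np.isnan(ipv) | np.isnan(inv) | ((ipv == 0) & (inv == 0))
    ratio = np.where(dead, np.nan, ratio)
    return NormalizedChip(ip.with_values(ratio), ip_total, input_total, offset)


def quantile_normalize(tracks: list[BinnedTrack]) -> list[BinnedTrack]:
    """Map each track's values onto the rank-wise mean distribution.

    Ranks are ordinal with a deterministic (stable, genomic-order) tie-break,
    so every output shares an identical multiset of values and within-track
    rank order is preserved. Windows missing in any track are dropped from
    all tracks (logged).
    """
    if len(tracks) < 2:
        raise ValueError("quantile normalization needs at least 2 tracks")
    grid = tracks[0]
    for t in tracks[1:]:
        if not t.same_grid(grid):
            raise ValueError("tracks are on different window grids")
    mat = np.stack([t.values for t in tracks])
    ok = ~np.isnan(mat).any(axis=0)
    n_drop = int((~ok).sum() - np.isnan(mat).all(axis=0).sum())
    if n_drop > 0:
        log.info("quantile_normalize: dropping %d windows with partial data", n_drop)
    sub = mat[:, ok]
    order = np.argsort(sub, axis=1, kind="stable")
    target = np.sort(sub, axis=1).mean(axis=0)
    out = []
    for i, t in enumerate(tracks):
        vals = np.full_like(t.values, np.nan)
        ranked = np.empty(sub.shape[1])
        ranked[order[i]] = target
        vals[ok] = ranked
        out.append(t.with_values(vals))
    return out


def loess_smooth(track: BinnedTrack, span: float = 0.05) -> BinnedTrack:
    """Loess (locally weighted linear regression) per chromosome.

    Fits value against window midpoint independently on each chromosome and
    evaluates at every non-missing midpoint; missing windows stay missing.
    Chromosomes with fewer than 5 observed windows pass through unsmoothed.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    values = track.values.copy()
    mids = track.midpoints()
    for chrom, sl in track.chrom_slices().items():
        v = track.values[sl]
        x = mids[sl]
        obs = ~np.isnan(v)
        if obs.sum() < 5:
            if obs.sum() > 0:
                log.info("loess: %s has %d points, passed through", chrom, obs.sum())
            continue
        sm = lowess(v[obs], x[obs], frac=span, it=1, xvals=x[obs])
        out = np.full_like(v, np.nan)
        out[obs] = sm
        values[sl] = out
    return track.with_values(values)


def replication_timing(
    early: BinnedTrack | list[BinnedTrack],
    late: BinnedTrack | list[BinnedTrack],
    span: float = 0.05,
    offset: float = 0.5,
    quantile: bool = True,
    log_ratio: bool = True,
) -> ReplicationTiming:
    """Smoothed early/late replication-timing track from fraction counts.

    Per replicate: RPM-scale early and late counts (with pseudocount) and
    form log2(early_rpm / late_rpm). Ratios are quantile normalized across
    replicates (when >1), loess-smoothed per chromosome and averaged.
    """
    earlies = early if isinstance(early, list) else [early]
    lates = late if isinstance(late, list) else [late]
    if len(earlies) != len(lates):
        raise ValueError("early/late replicate counts differ")
    ratios = []
    for e, l in zip(earlies, lates):
        if not e.same_grid(l):
            raise ValueError("early and late tracks are on different grids")
        etot = np.nansum(e.values)
        ltot = np.nansum(l.values)
        r = ((e.values + offset) / etot) / ((l.values + offset) / ltot)
        r = np.where(np.isnan(e.values) | np.isnan(l.values), np.nan, r)
        ratios.append(e.with_values(np.log2(r) if log_ratio else r))
    if quantile and len(ratios) > 1:
        ratios = quantile_normalize(ratios)
    smoothed = [loess_smooth(r, span) for r in ratios]
    stack = np.stack([s.values for s in smoothed])
    n_obs = (~np.isnan(stack)).sum(axis=0)
    mean_vals = np.where(
        n_obs > 0, np.nansum(stack, axis=0) / np.maximum(n_obs, 1), np.nan
    )
    meta = {
        "replicates": len(ratios),
        "span": span,
        "offset": offset,
        "quantile_normalized": bool(quantile and len(ratios) > 1),
        "log2_ratio": log_ratio,
    }
    return ReplicationTiming(ratios[0].with_values(mean_vals), ratios, meta)
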
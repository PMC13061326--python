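"""Domain-level analysis: chromatin classification of PMDs, hypermethylation
calls, scale-regions pileup matrices, decile summaries and the exact tests
used on domain counts.

PMDs are split into H3K9me3-marked and H3K27me3-marked classes by k-means
(k=2) on their per-domain mean IP/input enrichments. A PMD is called
hypermethylated when its mean methylation rises by at least a threshold
(default 5 percentage points) between two conditions, boundary inclusive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .genome import GenomicInterval
from .segmentation import Domain
from .tracks import BinnedTrack, interval_means

log = logging.getLogger(__name__)


@dataclass
class PmdClassification:
    """Per-PMD mark means and class label ('K9-marked' or 'K27-marked')."""

    table: pd.DataFrame  # columns: chrom, start, end, mean_k9, mean_k27, label
    centroids: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def labels(self) -> list[str]:
        return list(self.table["label"])


def classify_pmds(
    pmds: Sequence[Domain],
    k9_track: BinnedTrack,
    k27_track: BinnedTrack,
    seed: int = 0,
    n_init: int = 25,
) -> PmdClassification:
    """k-means (k=2) on per-PMD (mean H3K9me3, mean H3K27me3) enrichment.

    Features are z-scored before clustering; the cluster whose centroid has
    the higher H3K9me3 mean (original units) is labelled 'K9-marked', the
    other 'K27-marked', so labels never depend on seed or input order.
    """
    if len(pmds) < 2:
        raise ValueError("need at least 2 PMDs to classify")
    ivs = [d.interval for d in pmds]
    k9 = interval_means(k9_track, ivs)
    k27 = interval_means(k27_track, ivs)
    if np.isnan(k9).any() or np.isnan(k27).any():
        raise ValueError("PMD without mark coverage; cannot classify")
    feats = np.column_stack([k9, k27])
    z = (feats - feats.mean(axis=0)) / np.where(feats.std(axis=0) > 0, feats.std(axis=0), 1)
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed).fit(z)
    k9_by_cluster = [k9[km.labels_ == c].mean() for c in (0, 1)]
    k9_cluster = int(np.argmax(k9_by_cluster))
    labels = ["K9-marked" if l == k9_cluster else "K27-marked" for l in km.labels_]
    table = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in ivs],
            "start": [iv.start for iv in ivs],
            "end": [iv.end for iv in ivs],
            "mean_k9": k9,
            "mean_k27": k27,
            "label": labels,
        }
    )
    return PmdClassification(table, centroids=km.cluster_centers_)


def call_hypermethylated(
    domain_meth_wt: Sequence[float],
    domain_meth_ko: Sequence[float],
    threshold_pp: float = 5.0,
) -> pd.DataFrame:
    """Flag domains whose mean methylation gains >= threshold_pp points.

    Returns a DataFrame with delta (KO - WT, percentage points) and a boolean
    `hyper` column; the threshold is inclusive (delta == threshold is hyper).
    Domains lacking a defined mean in either condition are excluded (logged).
    """
    wt = np.asarray(domain_meth_wt, dtype=float)
    ko = np.asarray(domain_meth_ko, dtype=float)
    if wt.shape != ko.shape:
        raise ValueError("condition mean vectors differ in length")
    ok = ~(np.isnan(wt) | np.isnan(ko))
    if (~ok).sum():
        log.info("call_hypermethylated: %d domains lack a mean; excluded", (~ok).sum())
    delta = ko - wt
    return pd.DataFrame(
        {
            "index": np.arange(len(wt))[ok],
            "meth_wt": wt[ok],
            "meth_ko": ko[ok],
            "delta": delta[ok],
            "hyper": delta[ok] >= threshold_pp,
        }
    )


@dataclass
class PileupMatrix:
    """Scale-regions matrix: upstream flank | scaled body | downstream flank."""

    matrix: np.ndarray  # (n_domains, 2*flank_bins + body_bins)
    domains: list[GenomicInterval]
    flank_bins: int
    body_bins: int
    rank_key: Optional[np.ndarray] = None

    def column_means(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.matrix, axis=0)


def pileup_matrix(
    domains: Sequence[Domain] | Sequence[GenomicInterval],
    track: BinnedTrack,
    body_length: int = 1_000_000,
    binsize: int = 10_000,
    flank: int = 1_000_000,
    rank_key: Optional[Sequence[float]] = None,
) -> PileupMatrix:
    """Scale-regions pileup: bodies resampled to body_length, flanks native.

    Each domain body is divided into body_length/binsize equal sub-intervals
    (overlap-weighted track means); flanks are taken at native binsize up to
    `flank` bp, NaN beyond chromosome ends. Rows are ordered by descending
    rank_key when given (stable sort; ties keep input order); no row is ever
    dropped. A domain shorter than one bin contributes its overall mean to
    every body column (logged).
    """
    ivs = [d.interval if isinstance(d, Domain) else d for d in domains]
    if not ivs:
        raise ValueError("no domains supplied")
    body_bins = body_length // binsize
    flank_bins = flank // binsize
    chrom_sizes = {w.chrom: 0 for w in track.windows}
    for w in track.windows:
        chrom_sizes[w.chrom] = max(chrom_sizes[w.chrom], w.end)
    n = len(ivs)
    mat = np.full((n, 2 * flank_bins + body_bins), np.nan)
    for i, iv in enumerate(ivs):
        csize = chrom_sizes.get(iv.chrom, iv.end)
        up = [
            GenomicInterval(iv.chrom, s, s + binsize)
            for s in range(iv.start - flank, iv.start, binsize)
            if s >= 0 and s + binsize <= csize
        ]
        up_pad = flank_bins - len(up)
        if up:
            mat[i, up_pad:flank_bins] = interval_means(track, up)
        if iv.length < binsize:
            log.info("pileup: domain %s:%d-%d shorter than one bin", iv.chrom, iv.start, iv.end)
            mat[i, flank_bins : flank_bins + body_bins] = interval_means(track, [iv])[0]
        else:
            edges = np.linspace(iv.start, iv.end, body_bins + 1)
            body = [
                GenomicInterval(iv.chrom, int(edges[k]), max(int(edges[k + 1]), int(edges[k]) + 1))
                for k in range(body_bins)
            ]
            mat[i, flank_bins : flank_bins + body_bins] = interval_means(track, body)
        down = [
            GenomicInterval(iv.chrom, s, s + binsize)
            for s in range(iv.end, iv.end + flank, binsize)
            if s >= 0 and s + binsize <= csize
        ]
        if down:
            mat[i, flank_bins + body_bins : flank_bins + body_bins + len(down)] = (
                interval_means(track, down)
            )
    key = None
    if rank_key is not None:
        key = np.asarray(rank_key, dtype=float)
        order = np.argsort(-key, kind="stable")
        mat = mat[order]
        ivs = [ivs[k] for k in order]
        key = key[order]
    return PileupMatrix(mat, ivs, flank_bins, body_bins, key)


def decile_analysis(
    value_track: BinnedTrack,
    covariate_track: BinnedTrack,
    n_bins: int = 10,
) -> tuple[pd.DataFrame, float, float]:
    """Per-decile value summaries plus window-level Spearman correlation.

    Windows are ranked by the covariate (ties broken deterministically by
    genomic order) and split into n_bins equal-size groups. Returns
    (summary table, rho, p); rho/p are computed over windows, not decile
    means. Raises on a constant covariate.
    """
    if not value_track.same_grid(covariate_track):
        raise ValueError("tracks are on different window grids")
    v, c = value_track.values, covariate_track.values
    ok = ~(np.isnan(v) | np.isnan(c))
    if ok.sum() < n_bins:
        raise ValueError(f"need at least {n_bins} jointly observed windows")
    v, c = v[ok], c[ok]
    if np.ptp(c) == 0:
        raise ValueError("constant covariate: decile assignment undefined")
    order = np.argsort(c, kind="stable")  # stable = genomic-order tie-break
    decile = np.empty(len(c), dtype=int)
    decile[order] = np.arange(len(c)) * n_bins // len(c)
    df = pd.DataFrame({"decile": decile + 1, "value": v, "covariate": c})
    summary = (
        df.groupby("decile")["value"]
        .agg(n="count", mean="mean", median="median",
             q25=lambda s: s.quantile(0.25), q75=lambda s: s.quantile(0.75))
        .reset_index()
    )
    rho, p = stats.spearmanr(c, v)
    return summary, float(rho), float(p)


def fisher_exact(
    table: Sequence[Sequence[int]], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table -> (odds ratio, p).

    Two-sided p sums hypergeometric tables at most as probable as the
    observed one; one-sided alternatives give the corresponding tail.
    A zero row or column margin yields p = 1 with a warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if t.sum() == 0:
        raise ValueError("empty table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("zero margin: Fisher p fixed at 1", stacklevel=2)
        return float("nan"), 1.0
    res = stats.fisher_exact(t, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test -> (statistic, p).

    Exact null distribution for small tie-free samples, tie-corrected normal
    approximation otherwise. Completely tied data give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        return float(len(a) * len(b) / 2.0), 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def spearman(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) -> (rho, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


def assign_genes_to_domains(
    genes: Sequence[GenomicInterval],
    domains: Sequence[Domain] | Sequence[GenomicInterval],
) -> list[Optional[int]]:
    """Index of the domain wholly containing each gene; None if straddling.

    A gene is assigned only when fully contained in a single domain; genes
    crossing a domain boundary (or outside all domains) stay unassigned.
    """
    ivs = [d.interval if isinstance(d, Domain) else d for d in domains]
    by_chrom: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for i, iv in enumerate(ivs):
        by_chrom.setdefault(iv.chrom, []).append((i, iv))
    out: list[Optional[int]] = []
    for g in genes:
        hit = None
        for i, iv in by_chrom.get(g.chrom, ()):
            if iv.contains(g):
                hit = i
                break
        out.append(hit)
    return out


def class_comparison(
    values_by_class: Mapping[str, Sequence[float]]
) -> pd.DataFrame:
    """Pairwise two-sided rank-sum tests between named groups of values."""
    names = list(values_by_class)
    rows = []
    for i, x in enumerate(names):
        for y in names[i + 1 :]:
            stat, p = wilcoxon_rank_sum(values_by_class[x], values_by_class[y])
            rows.append({"group_a": x, "group_b": y, "statistic": stat, "p": p})
    return pd.DataFrame(rows)
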
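"""Synthetic methylome, ChIP-seq, repli-seq and time-course generator.

Generates a desk-scale genome whose statistical structure matches what the
analysis assumes: a bimodal window-level methylome in which megabase
low-methylation domains (PMDs) alternate with highly methylated domains
(HMDs); PMDs carry elevated H3K9me3 or H3K27me3 and replicate late; under
maintenance-methyltransferase (DNMT1) loss all domains lose methylation
except a planted minority of H3K9me3 PMDs that gain >= 5 percentage points
while losing H3K9me3 and gaining H3K36me2; and per-domain time courses
follow the kinetics module's exponential decay with class-specific de novo
rates.

Every stage draws from its own pseudo-random stream keyed by (seed, stage
name), so adding a stage never perturbs the draws of earlier stages and a
fixed seed gives bit-identical output.

Domain classes: ``HMD``, ``PMD-K9``, ``PMD-K27`` and ``PMD-hyper`` (the
planted gain-under-KO subset, H3K9me3-marked in the unperturbed state).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import (
    ExclusionSet,
    GenomeLayout,
    GenomicInterval,
    subtract_intervals,
    write_bed,
)
from .kinetics import KineticParams, decay_model
from .tracks import BinnedTrack, CpGRecord

PMD_CLASSES = ("PMD-K9", "PMD-K27", "PMD-hyper")
ALL_CLASSES = ("HMD",) + PMD_CLASSES

MARKS = ("H3K9me3", "H3K27me3", "H3K36me2", "H3K36me3")


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions.

    Lengths are log-normal in Mb given as (median, sigma_log, min, max).
    Methylation means are window-mode percentages; per-CpG noise is
    beta-binomial with the given concentration. ``noise=False`` switches
    every stochastic layer to its expectation (useful for exactness tests).
    """

    seed: int = 0
    chrom_names: tuple[str, ...] = ("chr1", "chr2")
    chrom_sizes: tuple[int, ...] = (25_000_000, 25_000_000)
    window: int = 10_000
    # domain geometry
    pmd_length_mb: tuple[float, float, float, float] = (0.7, 0.3, 0.35, 1.8)
    hmd_length_mb: tuple[float, float, float, float] = (0.45, 0.3, 0.25, 1.2)
    lead_hmd_mb: float = 2.0  # first domain of each chromosome, hosts the exclusion
    exclusion_length: int = 400_000
    k9_probability: float = 0.5  # P(K9-marked | PMD); rest K27-marked
    hyper_fraction: float = 0.2  # share of K9 PMDs planted as hypermethylated
    # methylome
    meth_mean_pct: dict = field(default_factory=lambda: {
        "HMD": 85.0, "PMD-K9": 55.0, "PMD-K27": 55.0, "PMD-hyper": 55.0})
    ko_delta_pp: dict = field(default_factory=lambda: {
        "HMD": -8.0, "PMD-K9": -15.0, "PMD-K27": -15.0, "PMD-hyper": 8.0})
    cpg_per_kb: dict = field(default_factory=lambda: {
        "HMD": 8.0, "PMD-K9": 6.0, "PMD-K27": 6.0, "PMD-hyper": 6.0})
    beta_concentration: float = 50.0
    read_depth_mean: float = 2.0
    # ChIP-seq (counts per window at the reference 10 kb bin)
    chip_depth: float = 50.0
    chip_enrichment: dict = field(default_factory=lambda: {
        "H3K9me3": {"HMD": 1.0, "PMD-K9": 3.0, "PMD-K27": 1.0, "PMD-hyper": 3.0},
        "H3K27me3": {"HMD": 1.0, "PMD-K9": 1.0, "PMD-K27": 3.0, "PMD-hyper": 1.0},
        "H3K36me2": {"HMD": 1.5, "PMD-K9": 1.0, "PMD-K27": 1.0, "PMD-hyper": 1.0},
        "H3K36me3": {"HMD": 2.0, "PMD-K9": 1.0, "PMD-K27": 1.0, "PMD-hyper": 1.0},
    })
    chip_enrichment_ko: dict = field(default_factory=lambda: {
        "H3K9me3": {"PMD-hyper": 1.0},   # hyper domains lose H3K9me3 under KO
        "H3K36me2": {"PMD-hyper": 2.0},  # and gain H3K36me2
    })
    # repli-seq
    repli_depth: float = 50.0
    repli_log2_offset: dict = field(default_factory=lambda: {
        "HMD": 1.2, "PMD-K9": -1.2, "PMD-K27": -1.2, "PMD-hyper": -1.2})
    # kinetics (per-day λ, ν per class)
    kinetic_rates: dict = field(default_factory=lambda: {
        "HMD": (0.45, 0.25), "PMD-K9": (0.5, 0.05),
        "PMD-K27": (0.5, 0.05), "PMD-hyper": (0.5, 0.12)})
    rate_jitter_sd: float = 0.1        # log-normal spread of per-domain rates
    timecourse_noise_sd: float = 0.03  # log-normal observation noise
    noise: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.hyper_fraction <= 1 or not 0 <= self.k9_probability <= 1:
            raise ConfigurationError("probabilities must be in [0, 1]")
        for lam, nu in self.kinetic_rates.values():
            if lam < 0 or nu < 0:
                raise ConfigurationError("kinetic rates must be non-negative")

    @property
    def layout(self) -> GenomeLayout:
        return GenomeLayout(self.chrom_names, self.chrom_sizes)

    def rng(self, stage: str) -> np.random.Generator:
        """Independent stream per (seed, stage name)."""
        return np.random.default_rng([self.seed, zlib.crc32(stage.encode())])

    def chip_fold(self, mark: str, klass: str, condition: str) -> float:
        if mark not in self.chip_enrichment:
            raise ValueError(f"unknown mark {mark!r}")
        fold = self.chip_enrichment[mark][klass]
        if condition == "KO":
            fold = self.chip_enrichment_ko.get(mark, {}).get(klass, fold)
        return fold


@dataclass
class GroundTruth:
    """Planted domains (tiling the genome minus exclusions) with class labels."""

    layout: GenomeLayout
    domains: list[GenomicInterval]
    classes: list[str]
    exclusions: ExclusionSet
    kinetic_params: dict = field(default_factory=dict)  # domain idx -> (λ, ν)

    def by_class(self, *names: str) -> list[GenomicInterval]:
        return [d for d, c in zip(self.domains, self.classes) if c in names]

    def pmds(self) -> list[GenomicInterval]:
        return self.by_class(*PMD_CLASSES)

    def hyper_set(self) -> list[GenomicInterval]:
        return self.by_class("PMD-hyper")

    def to_bed(self, path: str | Path) -> None:
        write_bed(self.domains, path, names=self.classes)


def _lognormal_length(rng, spec_mb, noise: bool) -> int:
    median, sigma, lo, hi = spec_mb
    if noise:
        x = median * np.exp(rng.normal(0.0, sigma))
    else:
        x = median
    return int(np.clip(x, lo, hi) * 1e6)


def generate_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Deterministic planted-domain layout for a config.

    Each chromosome opens with a long HMD carrying a centred exclusion zone,
    then alternates PMD/HMD with log-normal lengths until full; PMD classes
    are drawn K9/K27 and a `hyper_fraction` share of the K9 PMDs is relabelled
    PMD-hyper (at least one genome-wide). Domains are reported with exclusion
    zones subtracted, so they tile the genome minus exclusions.
    """
    rng = config.rng("layout")
    layout = config.layout
    lead = int(config.lead_hmd_mb * 1e6)
    min_pmd = int(config.pmd_length_mb[2] * 1e6)
    raw: list[tuple[GenomicInterval, str]] = []
    excl: list[GenomicInterval] = []
    for chrom, size in zip(layout.chrom_names, layout.chrom_sizes):
        if size < 2 * lead:
            raise ConfigurationError(
                f"{chrom} ({size} bp) too small for the requested domain layout"
            )
        mid = lead // 2
        excl.append(GenomicInterval(
            chrom, mid - config.exclusion_length // 2,
            mid + config.exclusion_length // 2))
        pos = 0
        raw.append((GenomicInterval(chrom, 0, lead), "HMD"))
        pos = lead
        next_pmd = True
        while pos < size:
            spec = config.pmd_length_mb if next_pmd else config.hmd_length_mb
            length = _lognormal_length(rng, spec, config.noise)
            end = min(pos + length, size)
            if size - end < min_pmd:  # absorb the remnant into this domain
                end = size
            klass = (
                ("PMD-K9" if rng.random() < config.k9_probability else "PMD-K27")
                if next_pmd
                else "HMD"
            )
            raw.append((GenomicInterval(chrom, pos, end), klass))
            pos = end
            next_pmd = not next_pmd
    k9_idx = [i for i, (_, c) in enumerate(raw) if c == "PMD-K9"]
    if not k9_idx:
        raise ConfigurationError("layout produced no K9-marked PMDs")
    hyper = [i for i in k9_idx if rng.random() < config.hyper_fraction]
    if not hyper:  # guarantee a planted hyper set
        hyper = [max(k9_idx, key=lambda i: raw[i][0].length)]
    raw = [
        (iv, "PMD-hyper" if i in set(hyper) else c) for i, (iv, c) in enumerate(raw)
    ]
    exclusions = ExclusionSet.build(excl, merge_gap=0, layout=layout)
    domains: list[GenomicInterval] = []
    classes: list[str] = []
    for iv, c in raw:
        for piece in subtract_intervals([iv], exclusions.intervals, layout):
            domains.append(piece)
            classes.append(c)
    kin: dict[int, tuple[float, float]] = {}
    jrng = config.rng("kinetic-jitter")
    for i, c in enumerate(classes):
        lam, nu = config.kinetic_rates[c]
        if config.noise and config.rate_jitter_sd > 0:
            lam *= np.exp(jrng.normal(0.0, config.rate_jitter_sd))
            nu *= np.exp(jrng.normal(0.0, config.rate_jitter_sd))
        kin[i] = (float(lam), float(nu))
    return GroundTruth(layout, domains, classes, exclusions, kin)


def _cpg_positions(config: SimulationConfig, truth: GroundTruth) -> list[tuple[int, np.ndarray]]:
    """Shared CpG positions per domain: list of (domain idx, sorted positions)."""
    rng = config.rng("cpg-positions")
    out = []
    for i, (iv, c) in enumerate(zip(truth.domains, truth.classes)):
        density = config.cpg_per_kb[c] / 1000.0
        n = int(round(iv.length * density)) if not config.noise else rng.poisson(
            iv.length * density)
        pos = np.unique(rng.integers(iv.start, iv.end, size=n))
        out.append((i, pos))
    return out


def simulate_methylome(
    config: SimulationConfig, condition: str = "WT"
) -> tuple[list[CpGRecord], GroundTruth]:
    """Per-CpG methylation calls for one condition ('WT' or 'KO').

    CpG positions are shared between conditions; each CpG's methylation
    propensity is beta-distributed around its domain-class mean (shifted by
    the class KO delta under KO), read depth is 1 + Poisson(mean - 1) and
    methylated reads binomial. With ``noise=False`` the propensity equals the
    class mean exactly and counts are rounded expectations, so window means
    are exact whenever mean*depth is integral.
    """
    if condition not in ("WT", "KO"):
        raise ValueError("condition must be 'WT' or 'KO'")
    truth = generate_ground_truth(config)
    rng = config.rng(f"methylome-{condition}")
    records: list[CpGRecord] = []
    for i, pos in _cpg_positions(config, truth):
        c = truth.classes[i]
        mean = config.meth_mean_pct[c]
        if condition == "KO":
            mean = mean + config.ko_delta_pp[c]
        p = np.clip(mean / 100.0, 1e-4, 1 - 1e-4)
        n = len(pos)
        if n == 0:
            continue
        if config.noise:
            conc = config.beta_concentration
            props = rng.beta(p * conc, (1 - p) * conc, size=n)
            totals = 1 + rng.poisson(max(config.read_depth_mean - 1, 0), size=n)
            meths = rng.binomial(totals, props)
        else:
            totals = np.full(n, max(int(round(config.read_depth_mean)), 1))
            meths = np.round(p * totals).astype(int)
        chrom = truth.domains[i].chrom
        records.extend(
            CpGRecord(chrom, int(q), int(m), int(t))
            for q, m, t in zip(pos, meths, totals)
        )
    order = {c: k for k, c in enumerate(config.chrom_names)}
    records.sort(key=lambda r: (order[r.chrom], r.pos))
    return records, truth


def _window_classes(
    config: SimulationConfig, truth: GroundTruth, bin_size: int
) -> tuple[list[GenomicInterval], list[Optional[str]]]:
    """Class of the domain covering each window midpoint; None in exclusions."""
    from .genome import make_windows

    windows = make_windows(truth.layout, bin_size)
    by_chrom: dict[str, list[tuple[GenomicInterval, str]]] = {}
    for iv, c in zip(truth.domains, truth.classes):
        by_chrom.setdefault(iv.chrom, []).append((iv, c))
    classes: list[Optional[str]] = []
    for w in windows:
        mid = (w.start + w.end) // 2
        hit = None
        for iv, c in by_chrom.get(w.chrom, ()):
            if iv.start <= mid < iv.end:
                hit = c
                break
        classes.append(hit)
    return windows, classes


def simulate_chip(
    config: SimulationConfig,
    mark: str,
    condition: str = "WT",
    bin_size: int = 10_000,
    replicate: int = 0,
) -> tuple[BinnedTrack, BinnedTrack]:
    """Poisson IP and flat input count tracks for one histone mark.

    IP window means are depth x class enrichment (condition-dependent); the
    input is flat at depth. Windows inside exclusion zones get zero counts in
    both tracks, mimicking unmappable regions. Total mapped reads for
    downstream scaling are the nominal n_windows x depth of each track.
    """
    if mark not in MARKS:
        raise ValueError(f"unknown mark {mark!r}; expected one of {MARKS}")
    if condition not in ("WT", "KO"):
        raise ValueError("condition must be 'WT' or 'KO'")
    truth = generate_ground_truth(config)
    rng = config.rng(f"chip-{mark}-{condition}-{bin_size}-{replicate}")
    windows, classes = _window_classes(config, truth, bin_size)
    scale = bin_size / 10_000.0
    depth = config.chip_depth * scale
    ip_mu = np.array(
        [0.0 if c is None else depth * config.chip_fold(mark, c, condition)
         for c in classes]
    )
    in_mu = np.array([0.0 if c is None else depth for c in classes])
    if config.noise:
        ip = rng.poisson(ip_mu).astype(float)
        inp = rng.poisson(in_mu).astype(float)
    else:
        ip, inp = ip_mu.copy(), in_mu.copy()
    return (
        BinnedTrack(windows, ip, bin_size),
        BinnedTrack(windows, inp, bin_size),
    )


def chip_nominal_total(config: SimulationConfig, track: BinnedTrack) -> float:
    """Nominal mapped-read total for a simulated track: windows x depth."""
    scale = track.bin_size / 10_000.0
    return len(track.windows) * config.chip_depth * scale


def simulate_repliseq(
    config: SimulationConfig,
    condition: str = "WT",
    bin_size: int = 10_000,
    replicate: int = 0,
) -> tuple[BinnedTrack, BinnedTrack]:
    """Early/late S-phase fraction counts with class-specific timing.

    Window means are depth x 2^(±offset/2) so the expected log2 early/late
    ratio equals the configured class offset: positive (early) in HMDs,
    negative (late) in PMDs — including hyper domains under KO, whose
    replication timing does not change.
    """
    if condition not in ("WT", "KO"):
        raise ValueError("condition must be 'WT' or 'KO'")
    truth = generate_ground_truth(config)
    rng = config.rng(f"repli-{condition}-{bin_size}-{replicate}")
    windows, classes = _window_classes(config, truth, bin_size)
    scale = bin_size / 10_000.0
    depth = config.repli_depth * scale
    off = np.array(
        [0.0 if c is None else config.repli_log2_offset[c] for c in classes]
    )
    dead = np.array([c is None for c in classes])
    e_mu = np.where(dead, 0.0, depth * 2.0 ** (off / 2.0))
    l_mu = np.where(dead, 0.0, depth * 2.0 ** (-off / 2.0))
    if config.noise:
        early = rng.poisson(e_mu).astype(float)
        late = rng.poisson(l_mu).astype(float)
    else:
        early, late = e_mu.copy(), l_mu.copy()
    return (
        BinnedTrack(windows, early, bin_size),
        BinnedTrack(windows, late, bin_size),
    )


def simulate_timecourse(
    config: SimulationConfig,
    timepoints: Sequence[float] = (0, 1, 2, 3, 4, 6, 12),
) -> pd.DataFrame:
    """Per-domain weighted-mean methylation series following the decay model.

    Each domain evolves by the kinetics closed form with its planted (λ, ν)
    and its class starting level, times multiplicative log-normal observation
    noise. Returns a long DataFrame (domain_id, class, day, weighted_mean_pct).
    Time points must include day 0 and be non-negative.
    """
    t = np.asarray(timepoints, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative time point")
    if not np.any(t == 0):
        raise ValueError("time points must include day 0")
    truth = generate_ground_truth(config)
    rng = config.rng("timecourse")
    rows = []
    for i, (iv, c) in enumerate(zip(truth.domains, truth.classes)):
        lam, nu = truth.kinetic_params[i]
        m0 = config.meth_mean_pct[c] / 100.0
        series = 100.0 * np.asarray(
            decay_model(KineticParams(lam, nu, m0), t), dtype=float
        )
        if config.noise and config.timecourse_noise_sd > 0:
            series = series * np.exp(
                rng.normal(0.0, config.timecourse_noise_sd, size=len(t))
            )
        for day, val in zip(t, series):
            rows.append(
                {
                    "domain_id": f"{iv.chrom}:{iv.start}-{iv.end}",
                    "class": c,
                    "day": float(day),
                    "weighted_mean_pct": float(val),
                }
            )
    return pd.DataFrame(rows)
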
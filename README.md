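# pmdkit

Domain-level analysis of cancer methylomes: segmentation of whole-genome
bisulfite data into **partially methylated domains (PMDs)** and **highly
methylated domains (HMDs)**, integration of ChIP-seq and repli-seq tracks,
chromatin-based PMD classification, calling of **hypermethylated PMDs**
between conditions, and modelling of DNA-methylation decay kinetics after
loss of the maintenance methyltransferase DNMT1.

It is written for epigenomics researchers who have CpG-resolution
methylation calls (bismark coverage / bedGraph), binned ChIP-seq counts and
repli-seq fraction counts, and want reproducible domain-level statistics
rather than genome-browser pictures. A bundled synthetic-data generator
produces a complete, realistic input set with known ground truth, so the
entire pipeline is testable on a laptop without any downloads.

## What it computes

**Segmentation.** Window-mean methylation (10 kb, read-count weighted:
100·Σmeth/Σtotal per window) is segmented with a two-state Gaussian HMM
(Baum–Welch fit, Viterbi decoding; missing windows bridged through the
transition structure). Low-state runs become PMDs, post-processed the way
PMD callers in this field do: trim each domain to its first/last CpG, bridge
domains closer than 2× the window size, complement to HMDs, excise assembly
gaps and centromeres (merged with 10 Mb slack), drop domains < 200 kb, merge
bookended neighbours. The same HMM called on 25 kb IP/input ratio windows
yields H3K9me3/H3K27me3 chromatin domains.

**Track processing.** ChIP-seq windows are normalized as
`((IP + 0.5)·10⁷/ipTotal) / ((IN + 0.5)·10⁷/inTotal)`; replication timing is
the loess-smoothed, quantile-normalized log₂ early/late RPM ratio (higher =
earlier).

**Domain statistics.** k-means (k = 2) splits PMDs into H3K9me3-marked vs
H3K27me3-marked classes; a PMD is *hypermethylated* when its mean
methylation rises ≥ 5 percentage points under DNMT1 loss (boundary
inclusive). Scale-regions pileup matrices (1 Mb body, 1 Mb flanks, 10 kb
bins), decile summaries, Fisher exact, Wilcoxon rank-sum and Spearman tests
operate on the resulting domain sets.

**Kinetics.** Each domain's methylated fraction follows
`dm/dt = −λ·m + ν·(1 − m)` (λ = maintenance-failure loss rate/day, ν = de
novo gain rate/day), with closed form
`m(t) = m∞ + (m0 − m∞)·e^(−(λ+ν)t)`, `m∞ = ν/(λ+ν)`. Fits are OLS of
log(weighted mean %) on day over the early log-linear window (days 0–6),
with the plateau read at day 12 — higher ν shows up as a shallower slope and
a higher final level.

## Worked example

```python
import pmdkit

cfg = pmdkit.SimulationConfig(seed=1)               # 2 x 25 Mb synthetic genome
recs_wt, truth = pmdkit.simulate_methylome(cfg, "WT")
recs_ko, _ = pmdkit.simulate_methylome(cfg, "KO")

pmds, hmds = pmdkit.call_pmds(recs_wt, cfg.layout, truth.exclusions, seed=1)
print(f"called {len(pmds)} PMDs and {len(hmds)} HMDs")
print(f"PMD recovery Jaccard: "
      f"{pmdkit.jaccard([d.interval for d in pmds], truth.pmds()):.3f}")

ivs = [d.interval for d in pmds]
wt = pmdkit.weighted_mean_methylation(recs_wt, ivs)
ko = pmdkit.weighted_mean_methylation(recs_ko, ivs)
calls = pmdkit.call_hypermethylated(wt, ko)         # >= 5 pp gain, inclusive
print(f"hypermethylated PMDs: {int(calls['hyper'].sum())} of {len(calls)} "
      f"(planted: {len(truth.hyper_set())})")

odds, p = pmdkit.fisher_exact([[60, 486], [3, 553]])
print(f"printed-table Fisher test: OR = {odds:.1f}, p = {p:.3g}")
```

prints

```
called 41 PMDs and 43 HMDs
PMD recovery Jaccard: 0.992
hypermethylated PMDs: 9 of 41 (planted: 9)
printed-table Fisher test: OR = 22.8, p = 6.33e-16
```

i.e. the HMM segmentation recovers the planted domain map at 99 % base-pair
overlap, the hypermethylation caller recovers the planted converted set
exactly, and the domain-count contingency test reproduces the reference
enrichment p-value.

The same stages are available from a shell via the `pmdkit` CLI
(`simulate`, `segment`, `chip-norm`, `repli`, `classify`, `hyper`,
`pileup`, `stats`, `kinetics`, `run`); `pmdkit run --simulate --outdir out`
executes everything end to end and writes a JSON report with per-stage
counts and SHA-256 output hashes. Reruns with the same seed are
byte-identical.

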
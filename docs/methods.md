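# Methods

## Coordinates and interval algebra

All coordinates are 0-based, half-open (BED convention); 1-based inputs are
converted at the reader boundary (the bismark-coverage reader takes the CpG
position as `end − 1`, which maps both the 1-based inclusive convention,
`start == end`, and 0-based half-open exports, `end == start + 1`, to the
same base). Chromosome order is always the layout/input order — nothing
sorts chromosome names lexicographically. Interval merging uses bedtools
`-d` semantics: two intervals merge when their gap is **≤** `max_gap`, so a
gap exactly equal to the threshold merges. This boundary convention is a
package decision (the closed/open choice at exactly the threshold is not
externally pinned) and is locked by tests.

Exclusion regions (assembly gaps limited to the heterochromatin, short-arm
and telomere classes, plus centromeres) are pooled and merged with a 10 Mb
slack before being subtracted from all domain calls, so whole
pericentromeric blocks are excised in one piece.

## Weighted methylation summaries

The methylation level of a window or domain is the read-weighted mean
100·Σmeth/Σtotal over contained CpGs, not the mean of per-CpG percentages.
The default coverage filter is ≥ 1 read (a ≥ 5 filter is appropriate only
for displaying single CpGs, where sampling noise dominates); it is
configurable everywhere. Windows without qualifying CpGs are missing, and
missing values are excluded from downstream statistics rather than imputed.
Binned fragment counting follows `bedtools coverage -counts` semantics: a
fragment increments every window it overlaps.

## PMD/HMD segmentation

Window-mean methylation (default 10 kb) is modelled with a two-state hidden
Markov model with Gaussian emissions per state. Count-level emission models
are the classical choice for PMD callers, but at the 1.6–2.4× coverage
regime this package targets, the window mean of dozens of CpGs is already
approximately Gaussian, and the window-level model is far easier to verify
against brute-force oracles; the acceptance surface here is planted-domain
recovery, not bit-compatibility with any particular caller.

Numerical choices: emission means initialised by k-means (k = 2) on the
observed values; transition matrix initialised at 0.99 on the diagonal;
Baum–Welch stops when the relative log-likelihood gain drops below 1e-4 or
after 200 iterations; variances floored at 1e-8; state 0 is relabelled to
the lower-mean state after fitting, making results label-symmetric across
seeds. Chromosomes are independent sequences sharing one parameter set.
Missing windows contribute no emission term in fitting or decoding, so a
data gap inside a domain never splits it — only a decoded state change
does. An all-constant track is returned as a flagged degenerate result
(zero domains) rather than a numerical failure.

Post-processing of decoded low-state runs, in order: trim each run to its
first and last contained CpG (a PMD therefore starts and ends on a CpG);
bridge runs whose gap is strictly < 2× the window size; complement within
chromosomes to HMDs; subtract exclusions; drop domains < 200 kb; merge
bookended same-kind neighbours. PMDs and HMDs are disjoint and, together
with exclusions and the dropped sub-200 kb remnants, tile the genome.
Chromatin-mark domains (25 kb IP/input windows) reuse the same HMM with the
high state as signal and no bridging or length filter, since those steps
are specific to the methylation caller.

## ChIP-seq and repli-seq processing

ChIP windows are scaled to counts per 10 million mapped reads with a 0.5
pseudocount added before scaling, then divided by the equivalently scaled
input; windows with zero coverage in all samples are masked. The ratio is
kept linear internally (log10 is only a display transform).

Replication timing: early/late fraction counts are RPM-scaled with the same
0.5 pseudocount (reused from the ChIP convention to avoid division by
zero), ratioed as log₂(early/late), quantile-normalized across replicates,
loess-smoothed per chromosome and averaged. The log₂ transform (rather than
a raw ratio) makes early/late symmetric around 0; the sign convention
"higher = earlier" is preserved either way. Quantile normalization operates
on the ratio tracks across samples, uses ordinal ranks with a stable
genomic-order tie-break (guaranteeing identical output multisets and
preserved within-track rank order), and drops windows missing in any
sample from all samples. Loess is local-linear (exact on linear trends)
with a default span of 0.05 per chromosome — the span is exposed because no
canonical value exists; 0.05 of a chromosome ≈ 1 Mb at 10 kb bins, matching
the megabase scale of replication-timing structure. Chromosomes with fewer
than 5 observed windows pass through unsmoothed. Note that RPM scaling
removes any genome-wide early/late imbalance by construction: timing values
are relative, and only regional contrasts are interpretable.

## Domain classification and hypermethylation calls

PMDs are clustered by k-means (k = 2) on their per-domain mean H3K9me3 and
H3K27me3 enrichments. Features are z-scored first (the two marks can sit on
different dynamic ranges) and 25 restarts with a fixed seed make the
partition deterministic; the cluster whose centroid has the higher H3K9me3
mean in original units is labelled K9-marked, so labels are independent of
seed and of input order.

A PMD is hypermethylated when mean methylation (KO) − mean methylation (WT)
≥ 5 **percentage points**, boundary inclusive — the threshold is applied on
the %mCpG scale, not as a relative 5 % change. Calling is monotone in the
threshold. Comparisons involving the K9-marked class are exposed both
including and excluding the hypermethylated subset, since both framings are
legitimate and conflating them changes the counts.

Pileup matrices follow scale-regions semantics: each domain body is
resampled to 100 bins (1 Mb / 10 kb), flanks taken at native bin size up to
1 Mb, NaN beyond chromosome ends; rows are ordered by a caller-supplied
rank key (descending, stable ties) and no row is ever dropped. Decile
analyses rank windows by the covariate with a deterministic genomic-order
tie-break; the Spearman correlation is computed over windows, never over
decile means. Fisher's exact test exposes `alternative` (two-sided sums
hypergeometric tables no more probable than observed; one-sided gives the
corresponding tail — enrichment-style claims are conventionally one-sided).
Rank-sum tests use the exact null for small tie-free samples and a
tie-corrected normal approximation otherwise. No multiple-testing
correction is applied to domain-level tests; they are reported as single
nominal p-values.

## Decay kinetics

The forward model `dm/dt = −λ·m + ν·(1 − m)` is the minimal ODE producing
both qualitative signatures of de novo activity: with ν = 0, log m(t) is
linear with slope −λ regardless of the starting level; with ν > 0, loss is
slower and plateaus at m∞ = ν/(λ+ν) > 0. λ + ν = 0 is degenerate (constant,
flagged). Fitting is deliberately not a joint nonlinear estimate of (λ, ν):
it is OLS of log(weighted mean %) on day restricted to days 0–6, where the
trajectory is near log-linear, plus the day-12 value as the final level —
slopes are in natural-log units per day. Domains with non-positive values
are excluded (logged) since the log does not apply.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
sequence-level reality. Defaults (all configurable, chosen once):

- Genome: 2 chromosomes × 25 Mb, 10 kb windows — large enough for roughly
  20 domains per PMD class, small enough for seconds-scale runs.
- Domain geometry: each chromosome opens with a 2 Mb HMD hosting a centred
  400 kb exclusion zone (a miniature centromere/gap), then alternates
  PMD/HMD with log-normal lengths (PMD median 0.7 Mb, HMD median 0.45 Mb,
  σ_log 0.3, clipped) — desk-scale versions of the ~1 Mb PMD lengths seen
  in real somatic methylomes. PMDs are K9- or K27-marked with probability
  0.5 each; 20 % of K9 PMDs are planted as hypermethylation-converting
  (at least one genome-wide).
- Methylome: window modes 85 % (HMD) and 55 % (PMD); per-CpG propensities
  beta-distributed around the class mean (concentration 50, the simplest
  model giving realistic window-level variance), read depth 1 + Poisson(1)
  (mean 2×, the low-coverage WGBS regime), CpG density 8/kb in HMDs vs
  6/kb in PMDs (realistic human density, PMDs CpG-poorer). CpG positions
  are shared between conditions. Under KO, HMDs lose 8 pp and PMDs 15 pp,
  except planted hyper domains which gain 8 pp.
- ChIP: Poisson counts, IP mean = 50/window × class enrichment (3× for the
  defining mark of each PMD class), flat input; under KO, hyper domains
  drop H3K9me3 to background and double H3K36me2 — the effect size for the
  H3K36me2 gain is an order-of-magnitude choice, as no quantitative value
  is externally pinned. Exclusion-zone windows get zero counts in all
  samples, exercising the dead-window filter.
- Repli-seq: Poisson early/late counts with expected log₂ ratio +1.2 in
  HMDs and −1.2 in PMDs; hyper domains stay late under KO.
- Time course: days {0, 1, 2, 3, 4, 6, 12} (fitting window plus plateau
  read-out; the grid is declared, not a claim about any specific
  experiment); class rates (λ, ν)/day: HMD (0.45, 0.25), PMD (0.5, 0.05),
  hyper PMD (0.5, 0.12), each jittered per domain by a 10 % log-normal;
  3 % multiplicative observation noise.

Randomness is a set of independent streams keyed by (seed, stage name), so
adding a stage never perturbs earlier draws and a fixed seed is
bit-reproducible. `noise=False` replaces every stochastic layer with its
expectation for exactness tests.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: no sequence context (no solo-WCGW effects), no
copy-number or mappability variation beyond the planted exclusion zones, no
cell-population heterogeneity, no coverage autocorrelation along the
genome, sharp (single-bp) domain boundaries, and class-homogeneous effect
sizes. Recovery scores on synthetic data are upper bounds on real-data
performance.

## Problem sizes and determinism

Default end-to-end runs use the 50 Mb synthetic genome (~335k CpGs, 5,000
windows, ~80 domains) and complete in a few seconds on one CPU; the
decoder-exactness check enumerates all 2^T paths for 200 random tracks of
T ≤ 12 windows. Pipeline runs with identical config and seed are
byte-identical (verified by SHA-256 of every output), and the resolved
configuration is written next to the outputs of every run.

## Known limitations

- The segmentation emission model is window-Gaussian; at extreme coverage
  sparsity (windows with 1–2 CpGs) a count-level emission model would be
  more faithful.
- Viterbi ties (exactly equal path probabilities, possible across long
  missing stretches) are broken by argmax order; any probability-maximal
  path is considered correct.
- Quantile normalization with ordinal ranks resolves ties by genomic
  order; average-rank interpolation would differ in the tied values.
- No spike-in (ChIP-Rx) scaling; IP/input normalization assumes matched
  chromatin composition.
- The kinetics fit assumes the day 0–6 window is log-linear; strongly
  plateauing domains (very high ν) bias the slope toward zero — an
  inherent property of the slope-plus-plateau summary, not of this
  implementation.
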
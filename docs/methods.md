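# Methods

This note documents the models, parameter choices, and numerical decisions
behind each stage, what the synthetic-data generator does and does not
emulate, and the known limitations.

## ERG oscillatory potentials

The OP band is isolated with a 4th-order Butterworth band-pass (75–350 Hz)
applied forward–backward (`sosfiltfilt`), i.e. an 8th-order zero-phase
response. Zero phase matters because the quantity of interest is timing:
a causal filter would add a frequency-dependent delay to every implicit
time. Passband gain at the band center exceeds 0.9 and DC/10 Hz leakage is
below 0.05, so the slow a/b-wave is suppressed by >400× in amplitude.

Peak detection uses `scipy.signal.find_peaks` with a prominence threshold
of 3 × the MAD (scaled by 1.4826 to estimate σ) of the filtered
pre-stimulus segment — the recording's own noise floor — with two guards:
peaks must also beat 1.25 × the largest prominence the pre-stimulus noise
itself produced (so a pure-noise trace returns an empty list rather than
labeling noise maxima), and peaks below 20% of the largest in-window
prominence are discarded (band-pass ringing sidelobes of a strong OP, which
matter only at very low noise). Peaks are labeled OP1, OP2, … in time
order; the first suprathreshold peak after onset is OP1 by convention.
Amplitude is trough-to-peak from the immediately preceding local minimum;
baseline-to-peak is the plausible alternative, and the choice only rescales
amplitudes, not timing.

a/b-wave extrema are located on a 2.5 ms moving-average copy of the raw
trace. An impulse-like excursion (raw extremum more than 2× the smoothed
value) snaps to the raw sample; a broad wave gets a least-squares parabola
vertex fitted over ±2 windows, which keeps b-wave timing stable to
~0.25 ms at 1 µV noise where a raw argmax wanders several ms along the flat
crest. Validity requires the a-trough to precede the b-peak and amplitudes
to clear 5× (a) / 8× (b) the noise σ — the b threshold is higher because
trough-to-peak spans of pure noise reach ~6.5σ over a 250 ms record.

Eye selection takes the side with the larger summed OP amplitude at the
dimmest flash; ties go to the left eye (documented, arbitrary).

## Functional hyperemia

A trial spans 35 s: baseline 0–10 s, flicker 10–25 s, post 25–35 s.
Kymographs sample each frame along a fixed cross-section with bilinear
interpolation. Caliber per frame is the longest contiguous run above a
single Otsu threshold computed over the whole kymograph — one threshold so
widths are comparable across frames; the longest run is robust to speckle
(a FWHM estimator is a reasonable alternative but not the default).
Columns are first rescaled by their 90th-percentile intensity (floored at
25% of the global level to keep vessel-free frames from amplifying noise):
without this, slow illumination drift moves edge pixels across the fixed
threshold and biases the stimulation-window width by several tenths of a
percent. Traces with >10% suprathreshold-empty frames are flagged
unusable.

Smoothing is a centered moving average with edge truncation; the default
window of 1.0 s (a design choice — the window length used in the original
recordings is not published) removes frame-rate jitter without flattening
the ~1 s dilation ramp. Percent dilation compares the 12.5–22.5 s mean to
the 0–10 s mean, giving the dilation 2.5 s to reach plateau; the statistic
is exactly `100·(stim−base)/base`, so px→µm conversion cancels. Group
percent reduction `100·(ctrl−case)/ctrl` is reported to one decimal.

## Bulk RNA-seq preparation

- **Low-count filter**: keep genes with total count ≥ 40 across samples
  (strictly "fewer than 40" removed). A per-sample variant exists behind a
  flag.
- **Size factors**: median-of-ratios against the all-nonzero-gene geometric
  mean reference, rescaled to geometric mean 1. Cross-checked in the test
  suite against the pyDESeq2 implementation to 1e-8 relative tolerance.
- **Stabilization**: log2(count/factor + 1). A simple started log rather
  than a fitted VST: at the depths simulated here the difference is
  immaterial for correlation-based downstream steps.
- **Batch removal**: per-gene least squares on condition plus sum-to-zero
  batch indicators; only the fitted batch component is subtracted, so
  condition effects pass through exactly and the operation is idempotent.
  Designs where a batch contains a single condition are rejected as
  confounded.
- **Outlier screening**: per round, PCA on the gene-standardized matrix;
  squared Mahalanobis distance of each sample's first-2 PC scores to their
  mean/covariance; removal beyond the chi-square(2) 0.95 quantile — the
  "95% confidence ellipse" in two dimensions. PCA is re-evaluated after
  each round (which is what catches an outlier masked by a larger one);
  the procedure stops after a round that removes nothing, or after two
  rounds. `n_pcs` and the confidence level are exposed. Expected behavior
  on clean data: ≈5% false removals per round, by construction.

## Differential expression

Counts are modeled per gene as NB(μ, α), Var = μ + αμ², with
log μ = Xβ + log s (size-factor offsets). The design uses cell-means
condition coding plus optional batch dummies; whether batch belongs in the
DE design is genuinely ambiguous in practice, so both are supported and
batch is included by default.

Dispersion is method-of-moments on normalized counts (pooled
within-condition variance, floored at 1e-8), shrunk toward a binned-median
trend over log mean with weight `min(1, 20/df)` on the trend — at the
sample sizes simulated here that is full-trend shrinkage, which is what
keeps the Wald test calibrated when per-gene raw estimates are noisy. The
shrinkage can be disabled. Fitting is IRLS (≤50 iterations, convergence at
1e-8); the Wald z uses the observed-information covariance and a normal
reference. No independent filtering, fold-change shrinkage, or outlier-
count replacement is applied. DEG thresholds are strict: padj < 0.05 and
|log2FC| > 0.32. BH adjustment preserves NaN p-values (all-zero or
non-converged genes) and excludes them from the test count.

## Co-expression network

Biweight midcorrelation uses Tukey biweights with truncation at 9 MADs and
falls back to Pearson deviations for zero-MAD variables. Signed adjacency
`((1+r)/2)^β` with β = 8 by default; the scale-free criterion (signed R² of
the log-log connectivity-frequency regression over 10 bins) is computed
and reported, and `pick_power` returns the smallest power exceeding the
target index (flagged best-effort if none does — planted-block covariance
is not scale-free, so on synthetic data the index typically peaks well
below 0.8). A non-positive index threshold degenerately accepts the first
candidate.

Mean-based topological overlap:
`TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / ((k_i+k_j)/2 + 1 − a_ij)`, with
dissimilarity 1 − TOM, verified against a brute-force double loop.

Module detection is a deliberate reimplementation of the dynamic tree-cut
family, not a port: average-linkage clustering of the TOM dissimilarity
with a **static branch cut** whose height decreases with `deep_split`
(0.995 − 0.01·deep_split; deep_split = 4 cuts at 0.955). The rationale:
random-correlation dissimilarities concentrate near 1 at these sample
sizes, while genuinely co-expressed blocks merge far below the cut, so a
cut just under 1 separates real branches and leaves noise genes in
sub-minimum clusters (unassigned, "grey"). Clusters under the minimum
module size (50) are unassigned; the maximum-size cap is off by default.
Bit-compatibility with the reference R cutter is explicitly not promised —
planted-structure recovery (ARI ≥ 0.8 on planted modules) is the contract.

Module eigengenes are first principal components of the gene-standardized
module submatrix, sign-aligned to correlate positively with mean module
expression and scaled to unit Euclidean norm. Modules whose eigengene
dissimilarity 1 − cor falls below the merge height (0.25) are merged
iteratively to a fixed point, keeping the larger module's label. kME is
the network correlation (bicor by default, Pearson optional) between each
gene and each ME. ME–trait association is Pearson r with a t-test on n−2
df, flagged at |r| > 0.3 and p < 0.05 (both strict); ME group contrasts
are least-squares cell-means fits with t-tests and BH adjustment across
modules per contrast. Module labels follow the conventional color palette
in decreasing size order.

## Enrichment

ORA p-values are upper-tail hypergeometric probabilities of at least the
observed overlap, BH-adjusted across sets; reported significance also
requires overlap ≥ 2 (the minimum-count convention for term reporting).
The universe defaults to the genes present in the supplied collection and
is configurable — whether to use the filtered expression universe instead
is left to the caller. Unique marker sets per class: filter at
log2FC > 0.25 and padj < 0.05 (strict), rank by log2FC descending with
ties broken by ascending padj then gene ID, keep the top k (1000 for cell
types, 2000 for NVU classes), then drop genes kept in more than one class;
the resulting sets are pairwise disjoint by construction. Percent
enrichment of a module is `100·|hub ∩ class set| / |hub|` with hub = module
genes at kME > 0.7 (strict).

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
the biology that produces it:

- **Counts**: NB(μ, α) with Var = μ + αμ² (α = 0.05 default), log-normal
  base means (median ≈ 90 counts, heavy right tail), log-normal library
  sizes (σ = 0.15), per-(gene, batch) N(0, 0.3) log2 batch shifts. The
  source study never describes its count distribution, so these are
  conventional values for a well-powered bulk experiment, not fitted ones.
- **DE genes**: a chosen group's means shift by ±de_lfc log2 units
  (random signs), planted disjointly from module genes.
- **Modules**: each module's samples share a standard-normal latent score;
  gene log2 means pick it up with weight `loading`. Latent scores are
  centered within condition groups — they model inter-individual,
  trait-like variation, so planted co-expression cannot masquerade as a
  treatment effect, which would make "false positive" ill-defined in FDR
  calibration. Module gene base means are floored at 50 counts so
  counting noise does not drown the planted covariance. Traits are
  `r·z + √(1−r²)·noise`, hitting correlation r in expectation.
- **Outliers**: whole-sample log2 shifts of `outlier_shift · σ_g · v_g`
  with v ~ N(0,1) — a coherent displacement in a random gene direction,
  detectable in PC space but in no single gene, matching what the
  Mahalanobis screen is designed to catch.
- **ERG**: difference-of-gamma slow wave (a-trough ≈ 15 ms, b-peak ≈
  60 ms, spectral content far below 75 Hz) plus Gaussian-windowed 140 Hz
  cosine bursts at the planted OP times and white noise.
- **Flicker trials**: planted width profile (1 s ramps around a 15 s
  dilated plateau) emitted either directly as a caliber trace with
  N(0, 0.3 px) jitter (fast path) or rendered as an image stack with
  logistic vessel-wall edges (0.75 px), additive noise, and a ±3% slow
  intensity drift. Both paths share ground truth.

What passing tests on this generator do **not** show: robustness to
count-model misspecification (zero inflation, gene-gene dispersion
heterogeneity), unbalanced or confounded designs beyond the rejected
cases, eye-movement artifacts in fundus video, or OP morphology changes
beyond timing/amplitude shifts. Conclusions about real data rest on the
methods' published track record, not on these simulations.

## Problem sizes and determinism

Validation suites run at desk scale by design: recovery simulations use
1,500 genes × 40 samples × 20 seeds for the transcriptomics chain, 100
seeds for OP timing, and 50 for dilation recovery. Every stochastic step
flows from an explicit `numpy.random.default_rng` seed; identical configs
give byte-identical outputs.

## Known limitations

- The NB Wald test uses a normal reference without a t correction;
  calibration at n ≲ 5 per group is untested.
- The branch cutter's static-height schedule is a simplification of
  adaptive tree cutting; deeply nested module structure (modules inside
  modules) will merge or vanish where the reference hybrid cutter might
  separate them.
- `detect_ops` numbering (OP1 = first suprathreshold peak) can disagree
  with protocols that count from a fixed post-flash latency when early
  OPs fall below noise.
- Kymograph extraction assumes registered frames; only the synthetic path
  guarantees that.
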
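# Methods

## The model

foldnet analyses the coordination of a four-gene protein-folding panel —
BAG2 (nucleotide-exchange co-chaperone), HSC70/HSPA8 (the chaperone itself),
STUB1/CHIP (E3 ubiquitin ligase) and MAPT (tau, the client) — across
Alzheimer's severity stages (control, incipient, moderate, severe; coded
1–4).  Expression values g are first mapped to x = log10(g + 1) and split
into one 4 × n_g panel matrix per severity group.

The central statistic is the eigen-spectrum of the **uncentered Gram
matrix** R = X Xᵀ, R[i, j] = Σ_k x_ik x_jk.  No centering or scaling is
applied: the mean expression level is deliberately part of the signal,
which is what distinguishes this statistic from covariance PCA.  Eigenvalues
are reported as fractions λ_i / Σλ, so the leading fraction measures how
much of the panel's joint (uncentered) energy lies on a single direction.
A rise in the leading fraction — in the emulated study system from ≈0.56 in
controls to ≈0.79 in the severe group — means the four genes' expression
collapses onto one dominant mode: one gene (or one combination) increasingly
dominates the panel's variation as the folding/degradation network loses
coordination.

Around this core sit four standard stages, each re-implemented at the level
the design requires:

* **Differential expression** — gene-wise two-sided independent t-tests at
  raw p < 0.05 (no multiple-testing correction, matching the original
  screen; a Benjamini–Hochberg column is available as a labelled extension).
  Welch's unequal-variance form is the default for groups of 7–9 samples;
  the pooled Student form is selectable.
* **Co-expression modules** — Spearman correlations raised to a soft power
  β (default 8) form a weighted adjacency |ρ|^β; average-linkage clustering
  on 1 − adjacency, a minimum module size of 30, an "unassigned" sink, and
  iterative merging of modules whose eigengenes (first singular vector of
  the gene-standardized submatrix) correlate above 1 − merge_cut (default
  merge_cut 0.25).
* **MMSE regression** — a from-scratch 4–32–1 network
  y = b + c·sigmoid(k + W x) with a linear output, trained by per-sample
  SGD on squared error; MMSE is the 0–30 cognitive score (lower = more
  impaired).
* **Disease classification** — each sample reduced to (sum, SD) of the four
  panel log-values, z-scored with training statistics, mapped to Gaussian
  similarities exp(−‖x−l‖²/2σ²) against the training samples as landmarks
  (σ² = 0.5), and separated by a from-scratch soft-margin hinge classifier;
  evaluated with sensitivity/specificity confusion counts, a threshold-sweep
  ROC curve and its trapezoid-rule area.

## Eigenvector orientation

Eigenvector signs are not identifiable from R alone: R is invariant under
X → −X, and any per-vector sign convention applied to both groups erases
exactly the cross-group information a "sign reversal" is meant to capture.
foldnet therefore keeps two orientations:

* **anchored** (`vectors_raw`) — each eigenvector is flipped so its dot
  product with the group's mean expression profile (column mean of X) is
  positive.  This is well defined given the data, is the orientation in
  which a planted direction flip between groups is recoverable, and is what
  `compare_leading_vectors` and the trajectory alignment matrix use.
* **reporting** (`vectors`) — largest-magnitude component positive, the
  convention used for printed tables, which are only comparable up to a
  global sign per column.

Externally reported eigenvector tables (`foldnet.reference`) are wrapped
with their printed orientation preserved; the published control and severe
leading vectors then anti-align (dot product ≈ −0.944), the reported
reversal.  Note a mathematical tension in the source system: log10(g+1)
data are nonnegative, so R is a nonnegative matrix whose leading eigenvector
can be chosen elementwise nonnegative (Perron–Frobenius), yet the published
control table's leading column has mixed signs; foldnet does not attempt to
reconcile this and simply compares vectors as given.

Degenerate (tied) eigenvalues are ordered by descending first-component
magnitude; vectors within a tied block are non-unique and only their span
is meaningful.

## Synthetic data: what is planted, what is not

All generators are pure functions of their seed.

**Panel generator.** For each group, X = Σ_k √λ_k q_k w_kᵀ + ε with
orthonormal gene-space directions q_k (q_1 the planted leading direction,
default the positive uniform vector), orthonormal sample-space vectors w_k
(w_1 the positive constant vector, so the planted leading direction carries
the mean component — the uncentered sense), λ_k proportional to the target
fractions, and ε i.i.d. Gaussian (default SD 0.02).  Defaults mirror the
emulated study: group sizes 9/7/8/7 and leading fractions drifting
0.56 → 0.58 → 0.60 → 0.79 (the non-leading fractions are a realistic choice
of spread, fixed once).  At zero noise the Gram fractions of the log-scale
matrices equal the targets to machine precision.

Two output forms exist.  The log-scale matrices are exact as constructed and
are what the spectrum-recovery and reversal simulations consume.  The
raw-intensity form applies g = 10^max(x,0) − 1 so the full read → log →
partition path is exercised; the max(x, 0) floor is unavoidable (raw
intensities are nonnegative) and it biases low-coordination spectra upward
— at a leading fraction of 0.56 the fluctuation components must exceed the
rank-1 baseline pointwise somewhere, so an elementwise-nonnegative matrix
with that exact spectrum does not exist at these group sizes, and the
control fraction recovered through the raw path runs ≈0.64.  The severe
target (0.79) is essentially unaffected (≈0.790).  For the same reason a
globally negated (sign-flipped) block cannot be represented as raw
intensities; reversal studies use the log-scale form.

**MMSE generator.** MMSE_i = clip(round(a₀ + a·x_i + N(0, 1)), 0, 30) with
default coefficients (8, 6, −5, −6) and intercept 10 over log-expression
values around 2.5 ± 0.5 — a strong linear relationship (signal SD ≈ 6
points of MMSE against 1 point of noise) of the kind the regression stage
assumes, spanning most of the 0–30 range.

**Classification generator.** (sum, SD) features are bivariate normal with
axis-aligned spread (SD 0.8 in sum, 0.1 in SD around means 10 and 0.4);
the patient mean is shifted by δ standard deviations per feature (Bayes
AUC = Φ(δ); δ = 1.5 gives ≈0.933).  Panel values are back-constructed so
each sample's sum and population SD match the planted features exactly (a
fixed zero-mean unit-SD pattern, randomly permuted per sample).  Class
sizes default to 180/181 to mirror the emulated training design.

**Module generator.** K modules (default 3 × 40 genes) each follow one
latent factor; a gene in module m is f_m + σε with σ = √(1/ρ − 1), giving
within-module correlation ρ (default 0.8); noise genes are independent.
Optionally the first module's factor is the standardized severity code, so
the module–trait stage has a planted positive.

What the generators do **not** emulate: probe-level Affymetrix noise,
gene-specific baselines and variances, batch effects, missingness or
outliers of real microarray data.  Passing recovery tests therefore shows
the estimators are correct and calibrated under their own assumptions, not
that the biological findings replicate.

## Numerical and design choices

* **Eigensolver**: symmetric `eigh` on (R + Rᵀ)/2; PSD is enforced by
  clipping eigenvalues at 0 (tolerance 1e−9 × trace on validation).
* **t-test degenerate input**: both groups constant with equal means →
  (t, p) = (0, 1); unequal means → (±∞, 0) with a warning.
* **Static tree cut**: the dendrogram is cut at the midpoint of the largest
  gap between consecutive sorted merge heights (searched in the upper half
  of the tree) — a deterministic stand-in for an adaptive tree cut.
  Separated module structure opens a wide within/between gap; structureless
  data yield no gap and fall through to the size filter (everything
  unassigned).  A fixed cut height remains configurable.
* **Scale-free fit**: connectivity k_i = Σ_j a_ij is binned (10 linear
  bins); R² of log10(frequency) on log10(mean k) with a negative slope
  required; the chosen β is the smallest candidate with fit ≥ 0.8.
* **Network training**: Glorot-uniform weight initialization, biases zero,
  min–max input normalization fit on training data only, per-sample SGD in
  a seeded shuffled order (bitwise-reproducible).  The default learning
  rate is 0.01 for 2,000 epochs: with raw 0–30 targets the per-sample
  gradient scale is ~2·|y−t|, and a rate of 0.05 drives the training MSE
  far below the noise floor while inflating held-out error (overfitting on
  cohorts of ~24 samples); 0.01 leaves the fit at the noise floor and
  generalizes.  Divergence (non-finite loss) raises with advice to lower
  the rate.  Held-out predictions are clipped to [0, 30] for reporting
  only; unclipped values are retained.
* **Max-margin training**: Pegasos-style stochastic subgradient steps on
  the scaled hinge objective (λ = 1/(Cn)), norm projection, and averaging
  of the second half of the iterates.  The bias rides along as a constant
  feature of value 5, so it is only lightly regularized (extra penalty
  b²/50); at 4·10⁵ iterations the hinge objective lands within 1% of a
  reference convex solver on 40-sample instances.  C defaults to 1, σ² to
  0.5, landmarks to the training set; the (sum, SD) features use the
  population SD (denominator 4), configurable to the sample SD.
* **ROC**: thresholds sweep the sorted unique decision values; tied scores
  collapse into one step; AUC is the trapezoid area and equals the
  Mann–Whitney U statistic divided by (positives × negatives).
* **Missing values**: tolerated in full matrices (as NaN) but rejected in
  panel submatrices; "already logged" detection is by the explicit scale
  flag only, never by value heuristics.
* **Probe collapse**: default policy keeps the probe with the highest mean
  (`max_mean`); `listed_probe` pins probes explicitly and `mean_collapse`
  averages; HSC70 ↔ HSPA8 aliasing is built in.  The chosen probes are
  returned as provenance.

## Problem sizes

The test suite and the acceptance script use: 100 random panels for the
spectrum/SVD identity; 200 replicates per planted-spectrum and reversal
study; 5,000 null genes (9 vs 7) for t-test calibration; 20 seeded
replicates of the MMSE cohorts (24 train / 8 test) and of the
classification cohorts (180/181 train, 31 test); and 3 × 40 planted module
genes plus 30 noise genes over 30 samples.  These sizes give stable means
(Monte-Carlo SE well below the tolerances used) while keeping a full run in
tens of seconds.

## Known limitations

* The simplified module stage is not a WGCNA port: no topological-overlap
  distance by default (available as an option), no dynamic tree cut, no
  blockwise decomposition for very large gene sets; reproducing a specific
  41-module decomposition of real data is out of scope.
* Reproducing the published real-data figures (held-out r = 0.915 on the
  GSE1297 cohort; AUC = 0.72 for GSE15222-trained / GSE1297-tested
  classification) requires the original accession data and their exact
  probe choices and splits, which are not distributed here; the pipeline
  accepts those inputs through `foldnet run-all --expression ... --metadata
  ...` but the package gates only on synthetic recovery.
* With ≤9 samples per group the leading fraction is a high-variance
  statistic; `bootstrap_leading_fraction` attaches a resampling interval
  but small-n caveats remain.
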
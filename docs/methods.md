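# Methods

`nmrfactor` analyses binned 1D ¹H NMR metabolomics data from a two-factor
animal study: a 2-level disease factor (control vs gastric mucosal lesion,
GML) crossed with a 3-level electroacupuncture factor (no treatment / SM
acupoints / GM acupoints). This note records the models, the numerical
choices, and what the synthetic data generator does and does not emulate.

## Preprocessing

**Referencing.** `reference_to_peak` applies a uniform ppm shift so the
maximum-intensity point inside a search window lands on the target position
(TSP at 0.0 ppm for urine, the lactate CH₃ resonance at 1.33 ppm for serum).
Ties between equal maxima break toward the lower-ppm point. Only this global
shift is supported; per-peak alignment is out of scope, and the simulator
defaults to zero peak jitter accordingly.

**Binning.** Fixed-width buckets over 0.5–9.0 ppm (serum) or 0.5–10.0 ppm
(urine), default width 0.002 ppm. Bins are half-open `[lo + kw, lo + (k+1)w)`
with the last bin closed; the bin statistic is the *sum* of point intensities
(bucket integral), so total signal inside the range is conserved. The bin
count is `floor((hi − lo)/w)` — 4750 bins for urine, 4250 for serum at the
default width.

**Exclusion windows.** Bins whose centers fall inside configured intervals
are dropped. Defaults: water 4.5–5.2 ppm for serum, water + urea 4.5–6.0 ppm
for urine. Real studies remove these windows by inspection and the exact
bounds are a judgment call, so both are configurable; additional "peak-free
region" removal is deliberately *not* automated — it is available only
through explicit config regions.

**Probabilistic quotient normalization (PQN).** Each row is first
integral-normalized to total 100 (an arbitrary documented constant), a
reference spectrum is formed (default: the median spectrum over all samples;
a named reference group or a single index are options — the method admits
any of these and the choice matters little for roughly balanced designs),
per-variable quotients row/reference are computed over bins where the
reference is positive, and the row is divided by the median quotient. The
estimated per-sample dilution is `(row total / 100) × quotient`, exposed as
`NormalizationResult.dilution_estimates` and identified only up to a common
scale. Note that re-applying PQN reproduces both the output matrix and the
quotients exactly (the integral step undoes the previous quotient division),
so the output is a fixed point; the second-pass quotients are *not* 1.

## Two-way ANOVA decomposition

The n×p matrix is decomposed per the general linear model

    X = 1 μ' + X_disease + X_EA + X_interaction + E

with an **unweighted cell-means parameterization**: the grand mean μ is the
mean of the six cell means, the disease effect at level a is the unweighted
mean over EA levels of the cell means at a minus μ (EA symmetric), the
interaction is the cell mean minus the additive fit, and the residual is the
within-cell remainder. This treats the unbalanced groups (7 vs 8 animals)
symmetrically, keeps every effect matrix cell-constant, and makes the
reconstruction identity exact by construction on any input. On balanced
designs the four submatrices are mutually orthogonal.

**Variance accounting.** SS(component) is the sum of squared entries of that
submatrix; percentages use the *four-component SS sum* as denominator so the
total is exactly 100.0 even when unbalancedness breaks orthogonality. The
grand mean is level, not variation, and is excluded.

**Effect filtering.** A factor-isolated dataset keeps one effect matrix plus
the residual (grand mean optional — irrelevant after the centering every
downstream model applies) and discards the other two, in the ANOVA-PCA /
ASCA tradition: the disease comparison models `μ + X_disease + E`, the
pairwise treatment comparisons model `μ + X_EA + E` restricted to GML
animals.

## Projection models

All models are NIPALS-based and authored here (no external PLS dependency).
X scaling defaults to mean-centering only, so covariance loadings retain
spectral shape; unit-variance and Pareto scaling are available by flag.
Binary class coding is 0/1 (single column), multi-class is one-hot; Y is
always column-centered.

**PLS-DA.** Per component: `w ∝ X'u` (unit norm), `t = Xw`,
`c = Y't/(t't)`, `u = Yc/(c'c)`, iterated to a relative score-change
tolerance of 1e-10 (cap 5000 iterations — multi-class fits with close
eigenvalues converge linearly and can need ~1000), then X and Y are deflated
by t. R²X and R²Y are the explained fractions of the scaled-X and centered-Y
sums of squares. For a single y column the iteration closes after one pass
and the first weight equals the normalized `X_c'y_c`.

**OPLS-DA** (two classes). Per orthogonal round on the current matrix:
`w ∝ X'y`, `t = Xw`, `p = X't/(t't)`, orthogonal weight
`w_o ∝ p − (w'p)w`, `t_o = Xw_o`, `p_o = X't_o/(t_o't_o)`, deflate by
`t_o p_o'`. The predictive component is a single-component PLS fit on the
filtered matrix. Orthogonal scores are exactly uncorrelated with the class
coding (`t_o'y = 0` analytically), and
R²X(pred) + Σ R²X(ortho) + R²X(residual) = 1. If no class-orthogonal
variation remains the round is skipped with a warning.

**Correlation loadings.** Per-variable covariance and Pearson r against the
binary class vector; constant columns get r = 0 with a `degenerate` flag;
variables inside declared noise regions get covariance and r set to 0 with a
`zeroed` flag (the explicit version of zeroing noise-region loadings by
hand). Both the back-scaled covariance and the predictive loading are
emitted, since conventions differ between software packages.

## Validation

**Cross-validated Q².** Stratified folds (default 8): within each class,
indices are shuffled by the seeded RNG and dealt round-robin, so assignment
is deterministic and class-balanced; classes smaller than the fold count
trigger a warning and relaxed stratification. Scaling and the Y center are
refit inside each training fold. Q² = 1 − PRESS/TSS with TSS measured
against the training-fold Y mean (alternatives differ by O(1/n)).

**Permutation tests.** `permutation_validate` permutes labels uniformly and
recomputes R²Y and Q² per permutation; empirical
p = (1 + #{null ≥ observed}) / (1 + n_perm). Designs with fewer than 20
distinct label arrangements are rejected as degenerate. Default 999
permutations; tests and the acceptance script use 49–199 to keep runtimes in
seconds.

**Validating effect-filtered models.** The kept effect matrix is estimated
*from* the labels later used for classification, so permuting labels on the
already-filtered matrix is badly anti-conservative — on pure noise it
produced p ≤ 0.05 in 3 of 10 runs. `pipeline.filtered_comparison` therefore
re-runs the decomposition and filtering inside every permutation, permuting
the tested factor *within strata of the other factor* (restricted
permutation, which also preserves every cell count and so never empties a
design cell). After this correction the null false-positive rate is
nominal (2/20 runs at α = 0.05 in the repository's own check).

## Univariate statistics

Per-bin group means and standard deviations (n−1 denominator), and unpaired
two-sample t-tests: Student pooled-variance by default (df = n_a + n_b − 2),
Welch–Satterthwaite by flag. Two-sided p-values; `significant` flags
p < α = 0.05 per variable without multiplicity correction, matching the
field's per-metabolite convention, while Benjamini–Hochberg q-values are
always emitted alongside so FDR control is one column away. Zero pooled
variance is handled explicitly: equal means give t = 0, p = 1; unequal means
give p = 0 with a `degenerate` flag. Tests run on the PQN-normalized matrix.

## Synthetic data generator

The generator defines the study conditions every test and the acceptance
script run under.

* **Design:** 46 samples in the unbalanced 2×3 layout 8/8/8/7/8/7
  (control/GML × none/SM/GM), exercising the unbalanced-design code paths.
* **Lineshape:** each metabolite is a sum of Lorentzian peaks (the natural
  solution-NMR lineshape), rendered on a uniform grid with 4 points per bin.
  The default panel has 15 metabolites spanning 0.5–10.0 ppm with standard
  positions (lactate CH₃ at 1.33 ppm, hippurate aromatics at 7.5–7.9 ppm, …).
* **Effects:** signed fractional changes composed multiplicatively on
  concentration — fold-change semantics. Defaults plant disease effects of
  ±20–50 % on 7 metabolites and treatment effects of ±15–40 % on 5 (SM
  slightly stronger than GM, mirroring a partially reversing treatment); no
  interaction effects by default.
* **Dilution:** per-sample log-normal factor, median 1, log-sd 0.2 — the
  multiplicative positive nuisance PQN exists to remove.
* **Noise:** additive Gaussian per grid point, sd 0.15. This value was
  calibrated once by Monte Carlo so the default pipeline's variance
  partition lands in the disease-dominant-with-large-residual regime typical
  of such studies (~40 % disease, ~50 % residual at 0.002 ppm bins); it was
  then frozen.
* **Peak jitter:** per-sample per-metabolite ppm shift, default 0 so the
  decomposition tests are exact; positive values emulate pH-driven drift.
* **Ground truth:** `SyntheticTruth` flags, per factor, every bin whose
  interval overlaps a ±2 HWHM (one FWHM) footprint of an effect-carrying
  peak. Beyond one FWHM a Lorentzian carries under 20 % of its apex height,
  so wider footprints would label bins holding no substantial share of the
  effect.

**What the generator does not emulate:** time-domain acquisition, phase and
baseline errors, J-coupling multiplet structure, water-suppression
artifacts, heteroscedastic (intensity-dependent) noise, and correlated
metabolite panels. Passing tests therefore demonstrate that the statistical
machinery recovers known structure under clean factorial conditions — not
that any biological conclusion transfers to real rat data, whose effect
sizes are unknown and unreproducible here.

## Problem sizes and runtime choices

Unit tests use coarse bins (0.01–0.05 ppm) where resolution is irrelevant;
end-to-end checks run the default 0.002 ppm resolution. Permutation counts
in tests and the acceptance script are 49–199 (the library default is 999).
The acceptance script's calibration blocks use 10 000 t-test replicates,
100 random decomposition datasets, 30-sample PQN recovery, and 20 simulated
datasets for the effect-isolation rate.

## Known limitations

* Serum and urine are processed as independent datasets; no cross-fluid
  integration.
* Only two crossed factors; no nested or three-way designs, no mixed models.
* OPLS-DA is strictly two-class; multi-class problems go through PLS-DA.
* The exploratory all-group PLS-DA is reported without a validation gate.
* `suggest_components` implements a simple Q²-gain stopping rule (< 0.05 per
  added component), a convention rather than an inferential procedure.
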
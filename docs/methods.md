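# Methods

This note documents the models, numerical choices and deliberate design
decisions behind `gradpain`, in the spirit of a package methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Connectopic mapping

**Fingerprints.** For a cleaned subject, the target region is everything in
the brain mask outside the ROI and a 1-voxel dilation ring around it (the
ring avoids self-correlation leakage; the ring width is configurable). The
target time-series matrix is demeaned per voxel and reduced by SVD; all
components above the numerical rank threshold (σₖ > 1e-10·σ₁) are kept, and
each left singular vector's sign is fixed so its spatial loading sum is
positive — a deterministic convention, since eta² similarity is *not*
invariant to per-component sign flips. Working against the
singular-value-weighted components preserves the Euclidean geometry of the
voxelwise covariance profiles exactly (orthogonal invariance; tested).
The fingerprint entries themselves are Pearson correlations of each ROI
voxel with each component, so they live in [−1, 1].

**Similarity.** Eta-squared between fingerprint rows, computed vectorized
with the identity Σₖ[(aₖ−mₖ)²+(bₖ−mₖ)²] = ‖a−b‖²/2. Degenerate pairs
(both profiles constant) are defined as similarity 1 and logged. Values are
clipped to [0, 1]; the unit diagonal is exact.

**Graph.** Mutual k-nearest neighbours on the zero-diagonal similarity,
k = max(6, 10% of N), with all neighbours tied at the k-th similarity
included (so a saturated similarity yields the complete graph). If the
result is disconnected, components are joined by *mutual-rank* bridges: the
cross-component pair minimizing rankᵢ(j) + rankⱼ(i), tie-broken by
similarity. Reciprocated rank matters because near-degenerate fingerprints
(see "Phantom degeneracies" below) produce strong one-sided similarities
that must not become bridges. All repairs are logged.

**Eigenmaps.** The generalized problem L v = λ D v (random-walk
normalization) is solved densely (`scipy.linalg.eigh`) up to 600 nodes and
by ARPACK shift-invert with a fixed start vector above that; both paths are
deterministic and agree to 1e-6 (tested). The eigenvectors of the n smallest
nonzero eigenvalues are each affinely rescaled to [0, 1] — required by the
downstream subdivision rule with cuts at 0.3/0.7 — and returned in
ascending-eigenvalue order with a lexicographic tie-break at eigenvalue
multiplicity 1e-10. Eigenvector sign is arbitrary, so maps are aligned to
the posterior→anterior world coordinate (positive correlation) before any
group averaging; averaging unaligned maps cancels to a flat map, a
documented hazard.

**Seed maps.** Per subdivision, the mean time series is correlated with all
brain voxels; correlations are Fisher z-transformed and standardized by the
sampling sd 1/√(T−3), thresholded at Z > 2, binarized, and averaged over
subjects into a probability map. The variance-stabilized Fisher Z was chosen
over a map-wise z-score of correlations (the alternative reading) because it
is the conventional subject-level statistic.

## Preprocessing

Stages run in a fixed order: confound regression → high-pass/detrend →
standardization (population 1/T sd throughout the package). High-pass is a
regression against a discrete cosine drift basis (all DCT-II frequencies
below 0.01 Hz) plus a linear trend — deterministic and free of filter edge
effects. The confound columns are themselves high-pass filtered before
regression: filtered regressors are exactly orthogonal to the drift basis,
so the sequential stages compose into a single projection and the pipeline
is idempotent (running it twice equals running it once; tested to 1e-8).
Without that orthogonalization, modular regression-then-filtering
reintroduces confound components — a known pitfall of sequential fMRI
denoising. Zero-variance voxels are flagged, zeroed, and removed from the
downstream mask with a logged count.

## Trend surface model

A third-order surface uses pure powers of the three coordinates — 9 spatial
regressors plus a nuisance intercept (the gradient's level carries no
information once maps are rescaled to [0, 1], so the intercept is excluded
from the feature vector). No cross terms: 3 axes × 3 powers. Coordinates are
centered at the ROI centroid and scaled to unit sd per axis before powers
are taken; mm values cubed are numerically ill-conditioned, and the stored
normalization makes coefficients comparable across subjects sharing a
common-space ROI. Coplanar axes are retained with a warning.

The fit is Bayesian linear regression with an isotropic Gaussian prior whose
precision α, together with the noise precision β, is chosen by evidence
(type-II ML) via the MacKay fixed point: α = γ/‖w‖², β = (N−γ)/RSS, with γ
the effective number of parameters, iterated on the eigendecomposition of
the Gram matrix (each update closed form). α is floored at 1e-12 and β
capped at 1e12, so a noiseless polynomial input converges to the OLS
interpolant (recovery to 1e-6; tested, and cross-checked against an
independent evidence-ridge implementation).

## QST scores

z_cold = z(CPT), z_heat = −z(HPT), z_mech = −z(ln MPT), composite = mean of
the three. Z-scores are computed within the analyzed cohort (not external
norms) with the population sd convention. The natural log for MPT is
cosmetic — z-scores are scale invariant, so the base only has to be fixed.

## Group statistics

Partial R² = (RSS_reduced − RSS_full)/RSS_reduced with reduced =
intercept + nuisance and full = reduced + the 9-parameter block, computed by
minimum-norm least squares so that collinear or duplicated predictors
degrade gracefully to R² = 0 rather than erroring; only n ≤ p is an error.
Nuisance coding: age in years, sex as a 0/1 indicator, menstrual-cycle day
as an integer with males at 0 (the sex indicator absorbs the offset).

Permutation inference is Freedman–Lane: reduced-model residuals are
permuted, added back to the reduced-model fit, and the statistic recomputed;
the p-value (1 + #{null ≥ observed})/(1 + B) includes the observed statistic,
guaranteeing validity and p > 0. The implementation vectorizes all B
permutations through two precomputed residual projectors. When B ≥ n! the
null is enumerated exactly (logged). Partial R² is inherently one-sided;
per-parameter partial correlations and the Mann–Whitney sex comparisons are
two-sided, the latter Bonferroni-corrected by the number of parameters per
hemisphere. Per-parameter p-values are reported both raw and
Bonferroni-adjusted. Quintile curves use the <20% / >80% composite
percentiles, per-subject bin means over normalized posteroanterior position,
and bootstrap-over-subjects 95% percentile bands.

## Synthetic data

**What the phantom emulates.** An ROI whose connectivity profile shifts
smoothly between two target networks: voxel i = (1−gᵢ)·s_A + gᵢ·s_B + σ·ε,
with g the voxel's position along one grid axis scaled to [0, 1], target
boxes carrying the pure signals, and the rest of the grid pure noise. The
latent signals are built from a band-limited DCT basis (0.015–0.08 Hz, the
resting-state band), so the 0.01 Hz high-pass leaves their geometry intact,
and they share a fixed in-sample correlation of 0.15 — large-scale network
time series are positively correlated through global fluctuations, and the
coupling also keeps the noise-free (rank-2) fingerprint geometry away from a
degenerate configuration (below). Default conditions: 24×12×7 grid, 500-voxel
ROI, T = 150 volumes at TR = 2.5 s, noise sd 0.5 relative to unit-variance
signals (a signal-dominated, high-SNR regime appropriate for a validation
phantom).

**What it does not emulate.** Hemodynamics, autocorrelated noise, motion,
spatial noise correlations, registration error, multi-site effects. Passing
tests therefore show that the *algorithms* recover what they are designed to
recover under clean conditions — not that real acquisitions at field
strength will behave as well.

**Phantom degeneracies.** With zero noise the target has rank 2 and each
fingerprint is a 2-vector on an arc. Eta² degenerates when a profile is
near-constant (its normalizing denominator collapses), which can happen at
one point of that arc; whether it does depends on the reflection geometry.
The deterministic SVD sign convention plus the fixed positive signal
coupling keep the arc away from that configuration, which is what makes the
noise-free dominant gradient *exactly* monotone in g. This is a property of
the degenerate noise-free corner only; at any realistic noise the target is
full-rank and the issue does not arise.

**Cohorts.** Subject variability is a monotone reparameterization g → g^a
with a ~ lognormal(0, 0.4) — one interpretable knob spanning
anterior-dominant (a < 1) to posterior-dominant (a > 1) gradient layouts.
The subject's "true" trend-surface coefficients θ(a) are the OLS fit of the
deformed g on the ROI basis. The latent sensitivity score is
β·θ(a) + 0.02·(age−mean) + 0.3·sexF + 0.01·cycle_day + N(0, 1). The default β
points along the gradient-axis polynomial block (direction (1, −0.6, 0.3)
on the axis' linear/quadratic/cubic terms) with magnitude 30, chosen once so
the planted signal sd is ≈ 0.7 score units under the default geometry — a
moderate effect of roughly a third of the score variance. Ages are
N(25.2, 3.5²) clipped to [18, 45]; sexes balanced; cycle day uniform 1–28
for women.

**Threshold back-generation.** The latent score is split into three modal
scores by adding per-subject noise centered across modalities; each modality
is standardized across the cohort, smoothly winsorized at 1.6 sd (a tanh
squash — QST thresholds occupy a bounded physiological range, and an
unbounded tail would let a very sensitive subject's back-generated cold
threshold cross their heat threshold), and re-standardized. Thresholds are
then affine (cold, heat) or log-affine (mechanical) in the final z-scores
using fixed population parameters — CPT 15.87 ± 8.15 °C, HPT
43.44 ± 3.36 °C, MPT mean 46.92 mN with arithmetic sd 47.92 mN mapped to
log-normal parameters. Because the scoring pipeline's z-transform inverts
these maps exactly, the recomputed composite equals the planted one to
machine precision, and the cohort means of cold and heat thresholds equal
the population values exactly (mechanical, being log-normal, matches in
expectation). Confound files are generated per subject but not mixed into
the phantom BOLD: the phantom's generative model is the exact two-signal
mixture above.

## Problem sizes

Defaults throughout the package and its acceptance script were chosen as the
smallest sizes at which the statistical claims are meaningful: 500-voxel
ROIs and T = 150 for gradient recovery (20 noisy seeds), cohorts of n = 60
with 200 permutations and 200 null / 50 planted replicates for calibration
and power, and 10,000 permutations as the default for real group analyses
(`n_perm` in the config). The full test suite and the acceptance script each
run in well under a minute on one core.

## Known limitations

- The graph construction (mutual kNN + mutual-rank bridging) is a standard
  Laplacian-eigenmaps choice, not a reimplementation of any specific
  toolbox's sparsification; it is configurable via `k`.
- Eta² similarity is sign- and location-sensitive; the component sign
  convention makes results deterministic but a different convention would
  give (slightly) different similarities. This is intrinsic to the measure.
- The trend surface ignores spatial autocorrelation of residuals; reported
  spatial R² is descriptive.
- Menstrual-cycle day for male participants is coded 0 with the sex
  indicator absorbing the offset; other codings would change the nuisance
  projection slightly.
- The quintile-curve abscissa is normalized posteroanterior position
  (voxel coordinate), one of several possible definitions.
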
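# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `renalmri`. It is the design record for
maintainers; the README gives the user-facing overview.

## Signal models and units

DWI voxels follow the two-compartment intravoxel incoherent motion form
S(b) = S0·[f·exp(−b·D*) + (1−f)·exp(−b·D)]; BOLD voxels follow
S(TE) = S0·exp(−TE/T2*). Internally every diffusion coefficient is in mm²/s
and every time in ms; the conventional reporting scales (D, ADC ×10⁻⁵ mm²/s;
D* ×10⁻² mm²/s; fD* ×10⁻⁴ mm²/s; f in %) are applied only when summaries are
rendered, via a single scale table (`REPORT_SCALE`). Keeping one internal
unit system and one conversion point is deliberate: mixed-scale parameter
passing is the classic source of IVIM software bugs.

The perfusion fraction is stored as a fraction in [0, 1] everywhere and
rendered as percent only at the reporting boundary.

Decay curves tolerate (finite) negative signal samples. The phantom adds
Gaussian noise to the magnitude signal, so a nearly fully attenuated voxel
can legitimately sample below zero; rejecting or clipping such samples would
bias the Gaussian-likelihood fits that consume the curves.

## The phantom

One 32 × 32 coronal slice holds a 13 × 9-voxel ellipse (~84–91 voxels,
accepted range 91 ± 12) representing the central slice of a rat kidney at
1.5 T with a 1.5 mm isotropic DWI voxel. The cortex is the one-voxel-wide
outline of the kidney mask (4-connected erosion residue) and the medulla the
interior — the same rule the region module applies to any loaded mask, so
phantom truth and derived regions agree by construction. The geometry check
rejects masks too thin to contain an interior.

Ground-truth parameters are constant within each region. Defaults are typical
rat renal values: baseline (repeatability) cortex f = 0.271,
D = 1.050 × 10⁻³ mm²/s, D* = 3.7 × 10⁻² mm²/s; medulla f = 0.234,
D = 1.330 × 10⁻³, D* = 4.2 × 10⁻²; T2* = 32.8 ms; each drug arm carries its
own pre-administration values and pre→post multipliers (per region for f, D,
D*, per BOLD timepoint for T2*), encoded in `renalmri.presets`. A uniform
whole-kidney mode (f = 0.269, D = 1.245 × 10⁻³, D* = 4.0 × 10⁻²) is used for
parameter-recovery validation so that the ROI median has a single known
truth.

Noise is additive white Gaussian on the magnitude signal, with standard
deviation σ = S0 / SNR and a default SNR of 20 — the level reported for this
class of acquisition; the DWI noise level is set equal to the BOLD one as a
documented assumption, and on-scanner signal averaging is absorbed into this
single effective σ (statistically equivalent for Gaussian noise). Rician
noise is deliberately not simulated: the fitting layer assumes Gaussian
errors and models no noise floor, and the phantom is meant to match the
fitting model's assumptions, not to stress them. At SNR 20 and the b-values /
echo times used, the magnitude-vs-Gaussian distinction is small anyway
(lowest kidney signal ≈ 5σ). What passing tests therefore demonstrate is
correctness of the estimation pipeline under its own noise model — not
robustness to Rician bias, motion, partial volume, or within-region
heterogeneity, none of which the phantom contains.

Challenge transforms multiply ground-truth fields per region. Where both a
whole-kidney and a cortex/medulla factor are given, the more specific region
wins; every voxel is scaled exactly once, and a transform followed by its
reciprocal restores the original field to machine precision.

## Fitting

**Perfusion-insensitive ADC.** Levenberg–Marquardt monoexponential fit on
b ≥ 200 s/mm² (inclusive threshold, flag-adjustable), initialised from the
two-point log-linear solution. With the 9-point scheme an exclusive b > 200
threshold would leave only two points and an exactly determined fit, so the
inclusive convention is the default. Unusable inputs (all non-positive
signals, LM failure) yield a non-converged result rather than an exception,
because voxelwise driving must not abort a map for one bad voxel.

**Segmented initialisation.** The high-b monoexponential fit gives D and an
intercept A = extrapolated S(b=0); f_init = 1 − A/S(0), clamped to [0, 1]
(clamping is flagged). D* carries no information at high b and is initialised
at 30 × D, a typical renal D*/D ratio. The residual standard deviation of the
high-b fit (SSR normalised by its single degree of freedom) is retained as
the default likelihood noise scale for the Bayesian fit.

**Bayesian IVIM fit.** Gaussian likelihood over all nine b-values with fixed
per-curve σ as above (an explicit σ can be supplied instead, which the test
suite uses to compare engines under identical likelihoods). Priors: uniform
f ∈ [0, 1]; uniform S0 ∈ (0, 2·S(0)]; uniform D ∈ [2 × 10⁻⁴, 5 × 10⁻³] mm²/s
(tissue water diffusion is bounded above by free-water diffusivity,
~3 × 10⁻³ mm²/s at body temperature); **log-uniform** D* ∈ [5 × 10⁻³, 0.3]
mm²/s. The log-uniform choice for D* is load-bearing: D* is a scale parameter
whose plausible values span orders of magnitude, and a linear-uniform prior
on so wide an interval places ~90 % of its volume in the fast tail
(D* > 0.1), where the nine-point likelihood is nearly flat. Measured on the
phantom at SNR 20, marginal posterior medians under a linear-uniform D* prior
overestimate D* severalfold and drag f and D with them; under the log-uniform
prior the ROI-median estimates are calibrated to within a few percent for f
and D and ~5 % for D*. The bounds still cover reported renal values with
better than five-fold margin on each side and are recorded in every fit's
diagnostics.

The default engine integrates the posterior on a deterministic grid. S0
enters the model linearly, so it is marginalised analytically: for each
(f, D, D*) cell the likelihood is Gaussian in S0 and its integral over the
uniform S0 prior is a closed-form truncated-Gaussian mass. The remaining
3-D box is evaluated in three passes of 40 nodes per axis: a prior-wide pass
(log-spaced on the diffusion axes), then two zoom passes on the 0.05–99.95 %
credible window of each marginal, linearly spaced. Node masses carry
trapezoidal quadrature weights times the prior density, marginal medians and
central 95 % intervals are read off interpolated CDFs, and the S0 median is
the weighted median of the per-cell conditional means (exact in the σ → 0
limit; well within grid resolution otherwise), with a moment-matched 95 %
interval. The engine is bit-for-bit reproducible and takes ~25 ms per voxel.
An MCMC engine (emcee, seeded) over the identical posterior is available as a
cross-check; both engines are tested against an independent brute-force 4-D
dense-grid posterior.

The per-curve σ estimate has a single degree of freedom and is floored at
10⁻⁴ of the signal scale. The floor keeps effectively noiseless curves
numerically well-posed on the grid (an unbounded likelihood would concentrate
the posterior below the resolving power of three refinement passes) without
visibly widening the posterior of genuinely noisy data. Marginalising σ under
a Jeffreys prior was considered and rejected for the default: the fixed-σ
likelihood is simpler, deterministic, and empirically calibrated at the study
SNR.

**Convergence labelling.** A least-squares fit is converged when the solver
succeeds with finite positive parameters. A Bayesian fit is non-converged
when ≥ 50 % of posterior mass sits in the outermost cells of the f or D prior
(boundary pile-up: the data do not identify the parameter inside the box), or
when the posterior medians are compartment-swapped (median D* < median D) —
the known failure mode of biexponential fits; there is deliberately no hard
D* > D constraint in the prior. Non-converged voxels keep their parameter
values in the map but are excluded from region medians and counted.

**T2\*.** Levenberg–Marquardt monoexponential fit in TE with no noise-floor
term (SNR > 20 at all echoes makes one unnecessary, and including one would
change the estimand). A fitted rate below 10⁻⁶/ms (constant signal, T2*
unbounded) is flagged non-converged.

## Regions and summaries

Cortex = mask minus its one-step 4-connected erosion; medulla = the erosion;
their union reconstructs the mask exactly, and an 8-connected variant is
available by flag. Region medians are computed over converged voxels only —
the median rather than the mean specifically to resist residual outliers —
and each summary row records the voxel and exclusion counts. BOLD summaries
are whole-kidney only by default: the 5 mm BOLD slice suffers partial-volume
mixing that makes a one-voxel cortical rim physically meaningless (the flag
can be overridden for synthetic studies). Median of an even count is the
usual midpoint average; with ROI sizes of ~28–91 voxels this matters at the
margin and is recorded for exactness. Kidneys can be excluded with a logged
reason; cohort statistics refuse to run if every kidney is excluded.

## Statistics

Within-subject repeatability CoV = 100·√((1/2N)·Σ (dᵢ/mᵢ)²) over paired
scans — the root-mean-square pairwise form standard for test–retest imaging
biomarkers. It is invariant to rescaling and to swapping scans within pairs;
pairs with non-positive means are dropped with a warning.

Pre/post DWI comparisons use the two-sided Wilcoxon signed-rank test at 5 %,
exact null for n ≤ 25 (when no tied magnitudes), normal approximation with
continuity correction otherwise; zero differences are removed before ranking
(Wilcoxon's original convention), and an all-zero set degenerates to p = 1
with a note. With the default six-kidney cohort the smallest attainable exact
p is 2/64 ≈ 0.031, so significance is reachable but only by unanimity — the
same small-n regime as a three-rat experiment.

The BOLD timecourse uses a one-way repeated-measures ANOVA (statsmodels
`AnovaRM`) with the kidney as subject; when the omnibus p < 0.05, paired
t-tests flag each post timepoint against baseline ("a") and against the
previous timepoint ("b"). Rat-level clustering of kidneys is not modelled —
kidneys are treated as independent subjects — and no multiple-testing
correction is applied across parameters or regions; both simplifications are
stated in every stats output. Percent-of-baseline series are reported per
unit with cohort mean ± standard error; ADC–D agreement is plain Pearson
correlation, reported as undefined (not an error) under zero variance.

## Pipeline and reproducibility

An experiment is one pydantic-validated YAML config: design (repeatability or
a drug arm), cohort size, phantom and fitting settings, schemes, master seed.
Per-stage seeds are derived from the master seed via `SeedSequence` over
CRC-32 of stage tags (process-stable, all below 2³¹) and logged. Identical
configs reproduce identical CSV/JSON outputs byte-for-byte. Each stage is
also exposed as a CLI verb over NIfTI/CSV/JSON files so stages can be run and
tested independently; exit code 2 marks validation errors, 1 runtime
failures.

Default problem sizes — one 32 × 32 slice, ~84 kidney voxels, six kidneys,
20 validation seeds, 40-node three-pass grids — were chosen as the smallest
sizes at which the cohort statistics are meaningful and recovery estimates
are stable; a full repeatability-plus-challenge run completes in a few
minutes on one CPU.

## Known limitations

* The phantom has piecewise-constant truth, no motion, no EPI distortion, no
  coil profile, no partial volume, and Gaussian (not Rician) noise; results
  quantify estimator behaviour, not acquisition artefacts.
* IVIM estimates where true f is small (medulla under some drug arms, ~7 %)
  are noisy and biased upward at SNR 20; this is a property of the model at
  this design, visible in the phantom results, and not corrected for.
* The fixed-σ likelihood understates posterior width when the single-dof σ
  estimate is low; point estimates (medians) are insensitive to this, but the
  reported credible intervals should not be over-interpreted.
* The repeated-measures ANOVA assumes sphericity and ignores the rat/kidney
  hierarchy; with three rats per arm a mixed-effects model would be
  under-identified anyway.
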
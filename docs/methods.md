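# Methods

## The generative model

`pulsevar.simcell` is a phenomenological generator of single-cell
pulse-labelling data. It makes no mechanistic claim about translation or
nutrient signalling; it reproduces the statistical structure that the
analysis pipeline assumes, so the pipeline can be tested quantitatively.

**Latent rate process.** Each cell carries a stationary, zero-mean, unit
Gaussian process X(t) with stretched-exponential autocorrelation

    ρ(Δt) = exp(−(Δt/τ)^β),   β ∈ (0, 2].

The instantaneous synthesis rate per µm of cell length is
`mean_rate · exp(s·X(t) − s²/2)` (mean one by construction, lognormal
marginals — the observed signal distributions are long-tailed). The kernel
is the characteristic function of a symmetric stable law, hence positive
definite throughout β ∈ (0, 2]; β = 1 recovers the Ornstein–Uhlenbeck
(Markov) case. A single exponential cannot reproduce the measured
dual-pulse correlation decay, which falls faster than exponentially between
20 and 50 min; the stretch exponent absorbs that. Paths are sampled on a
1-min grid (augmented with exact pulse endpoints) by one Cholesky
factorization of the grid correlation matrix, reused across all cells of a
sample; jitter up to 1e−8 is permitted on ill-conditioned grids.

**Growth and age structure.** Cells grow linearly from 7.5 µm at birth to
15 µm at division over a 250-min generation (conventional values for
exponentially growing fission yeast; the assay's source experiments report
times as fractions 0.15–0.25 of a generation equal to 40–60 min, giving
240–267 min — the midpoint is rounded to 250). Ages are drawn from the
steady-state age density of an exponentially growing culture,
f(a) ∝ 2^(−a/T) on [0, T] (uniform sampling is available for tests). Cells
whose cycle position at fixation falls in the final `binucleate_fraction`
(default 0.12) of the cycle are flagged binucleate; under the steady-state
age density this is a *population* fraction of 2·(2^(f−1) − ½) ≈ 0.087, not
f itself. Cells are not divided within an experiment window: for dual-pulse
horizons up to ~120 min of a 250-min generation, length simply extrapolates
linearly past the division length. Modelling division would split label
between daughters and couple the decorrelation curve to the cell cycle; the
assay's reported correlation anchors are reproduced without it, so the
simpler stationary picture is kept. This is a known limitation: in real
data, cells that divide between pulses contribute extra decorrelation.

**Measurement model.** A pulse on channel c over [t0, t0+P] deposits
`true_c = mean_rate · ∫ L(t)·exp(s·X(t) − s²/2) dt` (trapezoid, 1-min
steps). The observed signal is `true_c · exp(ε_c − σ_m²/2) + B_c` with
ε_c ~ N(0, σ_m²) independent per channel and B_c lognormal with median
`background_median` and log-SD `background_log_sd` (default 0.35, an
artifact choice). Background-only rows (`is_background = True`) emulate
cells fixed immediately after analogue addition and carry only B_c.
All random draws are standard normals scaled analytically, so a fixed seed
yields draws that are invariant to the noise parameters — this keeps the
calibration root-finders smooth (common random numbers) and makes every
table byte-reproducible for a fixed seed. Screen datasets derive one
substream per (strain, replicate) via `SeedSequence(seed, spawn_key=...)`,
so adding samples never perturbs existing ones.

## Calibration

Four reported anchors pin the free parameters: the dual-pulse R² values
0.85 / 0.46 / 0.12 at intervals 0 / 20 / 50 min (10-min pulses) and a
per-length-bin CV target of 0.31 (5-min pulse).

1. **Kernel (τ, β).** Treating r(l) = √(R²(l)/R²(0)) as the correlation at
   lag l gives the closed form β = ln(ln r₅₀ / ln r₂₀)/ln(50/20) ≈ 1.265,
   τ ≈ 50.9 min (`calibrate_kernel_closed_form`). The anchors, however,
   were measured with finite 10-min pulses, which smooth the correlation:
   the observable at lag l is G(l)/G(0) with G(l) = ∬ ρ(|l+u−v|) du dv over
   the pulse window. `calibrate_generator` therefore refines (τ, β)
   numerically so the *pulse-integrated* ratios match the anchors, giving
   τ ≈ 48.8 min, β ≈ 1.16. The analytic half-decay of the calibrated decay
   model, τ·(ln2/2)^{1/β} ≈ 22 min, matches the fitted pipeline value.
2. **Variance split.** The lognormal identity s_tot = √ln(1 + CV²) ≈ 0.303
   fixes the total observed log-spread; the delta-method split
   corr(0) = √R²(0) = s_bio²/(s_bio² + σ_m²) seeds the partition into
   biological and measurement components.
3. **Numerical refinement.** σ_m is then solved by Brent root-finding so the
   *simulated* simultaneous-pulse pipeline R² (including background,
   length normalization and OLS) equals 0.85, and s so the simulated
   median per-bin CV equals 0.31; two alternations converge
   (s ≈ 0.300, σ_m ≈ 0.076). The calibration simulations use 6,000 cells
   with a fixed internal seed, so `default_calibration()` is deterministic
   and is cached per process.

The background median defaults to 20% of the median noise-free 5-min pulse
signal of a median-length cell — an artifact choice, configurable, chosen so
background correction is a non-trivial pipeline step.

## Analysis conventions

* **Quartiles**: linear interpolation of order statistics, h = (n−1)p + 1
  (numpy's default), documented because QCD exact-match tests depend on it.
* **Length bins**: half-open [k·w, (k+1)·w) with edges at integer multiples
  of the width (w = 1 µm default), labelled by bin centre. Edge alignment is
  not fixed by the convention the assay reports (only the centre labels
  are); integer alignment is chosen for reproducibility.
* **Background subtraction**: scale by the background-sample median, then
  subtract the per-bin background median; bins lacking background cells
  fall back to the global median (logged). Negative corrected values are
  retained — quantile statistics tolerate them and clipping would bias low
  signals. The residual bias of the recovered mean incorporation is the
  background's median-vs-mean offset, below 2% at the default settings.
* **Decay fit**: R²(Δt) = R²₀·exp(−2(Δt/τ)^β), with R²₀ a free
  interval-independent attenuation (channel noise and background are
  per-channel and do not depend on the interval). Coarse grid search over
  (τ, β) with the optimal R²₀ solved linearly, then bounded least squares;
  parameters at the bounds are flagged.
* **Ranked groups**: deciles by default, sorted ascending with ties broken
  by cell id (deterministic, permutation-invariant); uneven remainders go
  to the lowest groups.
* **Convergence criterion**: the source experiments state the outcome
  (extreme groups regress to the mean within 40–60 min) but no criterion.
  Here an extreme decile has converged at the earliest interval where its
  *geometric* deviation |log(group mean / population mean)| falls below one
  third of its interval-0 value. The log scale is deliberate: the signal is
  multiplicative, and on the log scale both extreme deciles decay in
  proportion to the underlying rate correlation, whereas the arithmetic
  deviation of the low decile decays artificially slowly (concavity of
  1 − e^{−x}). The arithmetic variant and the threshold fraction are
  configurable.
* **Screen**: per-replicate QCD per strain, flagged against the wild-type
  mean ± 1.5·SD (sample SD over ≥2 replicates). Two signal conventions:
  per-cell mean signal divided by the sample median (flow-cytometry mode;
  the division leaves QCD unchanged but normalizes the tables), and OLS
  length-normalized raw signal (microscopy mode). No multiple-testing
  correction by default; a Benjamini–Hochberg helper exists. The paired
  replicate comparison is a paired t-test on differences; the protocol
  phrase "Welch's unequal variances paired t test" is contradictory (Welch
  applies to unpaired samples), so the unpaired Welch variant is available
  behind `method="welch"` and the choice is logged.
* **Feret diameter**: maximum pixel-centre distance via the convex hull
  (equal to the brute-force all-pairs maximum); no corner-to-corner +1
  correction. Rendered rods align their axis to a pixel row and their left
  tip to an integer column so the rendered Feret is within 1 px of
  `length_um × px_per_um` (15.3609 px/µm default).

## Problem sizes

Defaults used by the test suite and the reproduction script: 20,000 cells
for the single-pulse population profile; 10,000 cells per interval for the
0/20/50-min dual-pulse anchors; 5,000 cells per interval on fine interval
grids (13 intervals for the half-decay fit, 12 for parameter-recovery
sweeps of 50 independent runs); 20,000 cells per interval for decile
trajectories (decile means need ~3× tighter standard errors than the R²
curve); screens of 5 wild-type replicates plus planted strains at 1,000
cells per sample, with power estimated over 50 seeds. These sizes keep
every Monte-Carlo standard error several times smaller than the tolerance
of the check that consumes it.

## What the generator does and does not emulate

Emulated: long-tailed (lognormal) rate variability with CV > 30% at every
cell size; temporal autocorrelation matching the reported dual-pulse decay;
size-proportional incorporation; pulse-window integration; background
fluorescence with a dedicated background sample; multiplicative channel
noise; growth, steady-state age structure and binucleate stages; strain
variability modifiers with replicate-level jitter (on the mean rate and
background level — both leave QCD nearly invariant by scale invariance, so
wild-type replicate spread is realistic but small).

Not emulated: cell division during an experiment (see above), staining
chemistry, flat-field/illumination artefacts, segmentation errors,
cell-cycle-dependent rate modulation, and any mechanistic link between the
variability modifier of a strain and a gene. Consequently, passing tests
demonstrate that the *pipeline* recovers known ground truth under the
stated statistical structure — not that real populations satisfy that
structure.
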
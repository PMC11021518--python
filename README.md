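# pulsevar

Single-cell pulse-labelling variability analysis for rod-shaped yeast.

Protein synthesis in a cell depends on hundreds of coupled reactions, yet
single-cell measurements of metabolic-analogue incorporation (a 5–10 min
pulse of a clickable methionine analogue such as HPG or AHA, fluorescently
labelled after fixation) show that the net synthesis rate varies several-fold
between cells of the same size — and that each cell's rate wanders on a
timescale of tens of minutes. `pulsevar` implements the full analysis
pipeline for such experiments, together with a calibrated synthetic-data
generator, for computational biologists who want to test, extend or power
such analyses without access to raw imaging data:

* **simcell** — generative model: each cell carries a latent log-rate
  process X(t), a stationary Gaussian process with stretched-exponential
  autocorrelation ρ(Δt) = exp(−(Δt/τ)^β), β ∈ (0, 2]; a pulse deposits
  signal ∝ ∫ L(t)·exp(s·X(t) − s²/2) dt over the pulse window, observed with
  multiplicative lognormal channel noise and additive lognormal background.
  Cells grow linearly over the cycle and are sampled from the steady-state
  age distribution of an exponentially growing culture. The generator can
  also render cells as labelled spherocylinders in 16-bit TIFF images.
* **quant** — mask-based quantification: Feret diameter (pixel-centre
  convention), per-mask intensity statistics, nucleus counting by majority
  overlap, and configurable post-acquisition gates.
* **normalize** — background scaling by the background-sample median,
  per-1-µm-bin background subtraction, OLS length normalization, and
  per-length median normalization.
* **varstats** — quantiles, the quartile coefficient of dispersion
  QCD = (Q3 − Q1)/(Q3 + Q1), the coefficient of variation, and per-bin
  variability profiles.
* **dualpulse** — dual-label decorrelation: per-interval OLS R² between the
  two channel signals, a fit of R²(Δt) = R²₀·exp(−2(Δt/τ)^β) with its
  half-decay interval, and ranked-decile regression-to-the-mean
  trajectories.
* **screen** — replicate-thresholded variability screen: strains whose mean
  QCD leaves the wild-type mean ± 1.5·SD band are flagged high/low, plus
  paired replicate t-tests.

The generator is calibrated so that the *full* simulated pipeline reproduces
the reported anchors of the assay it emulates: dual-pulse R² of
0.85 / 0.46 / 0.12 at intervals of 0 / 20 / 50 min, and a per-size-bin CV of
~31% with a >3-fold long-tailed spread.

## Worked example

```python
from pulsevar import experiments, dualpulse

# Dual-pulse experiment: 10-min pulses, second label delayed 0/20/50 min.
res = experiments.decorrelation_analysis([0, 20, 50],
                                         n_cells_per_interval=10000, seed=1)
print(res["curve"])
fit = res["fit"]
print(f"half-decay = {fit.half_decay_min:.1f} min")
```

prints

```
 interval_min       r2    n
          0.0 0.842169 9125
         20.0 0.453220 9036
         50.0 0.110448 8994
half-decay = 21.8 min
```

Simultaneously pulsed channels are tightly correlated (R² ≈ 0.84); after a
20-min gap half the variance in the first measurement no longer predicts the
second (R² ≈ 0.45), and by 50 min the two measurements are nearly independent
(R² ≈ 0.11) — the single-cell synthesis rate decorrelates with a half-decay
of roughly 20 min. The single-pulse population profile shows the
complementary static picture:

```python
_, profile = experiments.wildtype_variability(n_cells=20000, seed=1)
print(profile[["bin_centre_um", "n", "cv", "qcd"]].round(3))
```

Every 1-µm cell-length bin has a CV above ~30% (median 0.326 here), i.e. the
spread is not explained by cell size.

A command-line interface mirrors the library:

```sh
pulsevar simulate --out cells.csv --n-cells 5000 --seed 1
pulsevar analyze-variability --cells cells.csv --out profile.csv
pulsevar dual-pulse --out results/ --intervals 0,20,50 --seed 1
pulsevar run --config experiment.yaml       # config-driven pipeline
```

## Layout

```
src/pulsevar/     library modules (simcell, quant, normalize, varstats,
                  dualpulse, screen, experiments, config, cli, plotting)
tests/            pytest suite, including end-to-end acceptance tests
docs/methods.md   model, calibration and design notes
scripts/          reproduction script
```
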
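# Methods

This note records the modelling assumptions, defaults and numerical choices
behind `laiproj`, and what the synthetic test bed does and does not show
about real data.

## The selection procedure

The unit of analysis is a region: a latitude band over which all series are
reduced to cosine-latitude area-weighted means of unmasked (and, when a
vegetation mask is supplied, vegetated) cells. The five study regions are
the globe and the bands 60–90° N, 30–60° N, 30° S–30° N and 30–60° S; cells
south of 60° S belong to the globe but to no sub-region. Regional means are
the default; the region abstraction also accepts single-cell "regions", so
grid-cell-level selection is possible but not the default.

Per region the sweep crosses 31 factor subsets × 4 datasets × 6 algorithms
= 744 candidates. Each candidate is evaluated by a **chronological holdout**:
fit on the first 80 % of historical months, score DISO on the final 20 %.
The split guards against trivially rewarding high-capacity learners with
in-sample fit; in-sample evaluation is available (`protocol="insample"`)
since the evaluation window of the original study design is not pinned down.
The holdout score is attached to the model; the selected optimum is then
refit on the full historical window before projection, which is standard
practice when the model form has already been chosen.

A candidate whose fit fails (too few samples, degenerate observations,
numerical failure) scores +∞ and is counted, never aborting the sweep.
Misuse of the sweep itself — misaligned indexes, unknown factor names —
raises immediately.

Ties are broken deterministically everywhere: among datasets by the
configured dataset order (ESMs first, then MME, then DISO-W), among
algorithms by the canonical order LR, SVR, RF, CNN, LSTM, Transformer, and
at the overall optimum by fewer factors first. Exact DISO ties are rare but
possible with +∞ sentinel scores.

## DISO

`DISO = sqrt((R² − 1)² + norMAE² + norRMSE²)`, with:

* **R²** defined as 1 − SS_res/SS_tot. It may be negative for
  worse-than-mean models, which correctly pushes DISO above 1; the squared
  Pearson correlation is available (`r2_kind="pearson2"`) because the two
  readings of "coefficient of determination" coexist in the skill-score
  literature.
* **norMAE / norRMSE** obtained by dividing MAE and RMSE by the mean
  absolute observation over the evaluation window, anchoring a perfect model
  at (1, 0, 0) and making the score dimensionless. A min–max normalisation
  across a candidate set is provided as an alternative
  (`normalize_indicator_sets`).
* Pairwise masking: a time step masked in either series is dropped from all
  three indicators. Constant observations, or observations with zero mean
  absolute value, are rejected as degenerate rather than silently scored.

## Ensemble weights

Inverse-DISO weights `w_l = (1/DISO_l) / Σ_k (1/DISO_k)` are computed in a
(region, algorithm) context: the DISO feeding the weight of dataset *l*
comes from a reference model fitted on *l* with that algorithm, using the
full five-factor set by default (`reference_combination` overrides). The
weight is shared by all five factors of the dataset. With any DISO exactly
zero the limit of the formula is taken: total weight 1 split equally among
the zero-scoring datasets. Because regional averaging is linear, applying
the weights to regional-mean series equals extracting from weighted cubes;
both routes are provided.

## Learners

Hyperparameters (all overridable via `LearnerSpec.hyperparams`):

| family | defaults |
|---|---|
| LR | ordinary least squares with intercept |
| SVR | RBF kernel, C = 10, ε = 0.1, standardised inputs |
| RF | 200 trees, unlimited depth, seeded |
| CNN | 12-month window, 16 random conv filters, kernel 3, tanh, mean-pool; ridge readout (α = 0.01) |
| LSTM | echo-state recurrence, 32 units, spectral radius 0.8, input scale 0.5; ridge readout |
| Transformer | 12-month window, model width 32, 2 random attention heads, sinusoidal positions; ridge readout |

The three sequence families are **random-feature / reservoir learners**:
their convolutional, recurrent and attention feature maps are fixed by the
seed and only the linear readout is trained (closed-form ridge with an
unpenalised intercept). This makes every learner exactly deterministic under
a fixed seed, fits a 744-model sweep in well under a minute per region on
one CPU, and preserves the family semantics relevant to the sweep — finite
window (CNN, Transformer) versus fading recurrent memory (LSTM). It also
guarantees the constant-target property exactly: constant y yields zero
readout weights and intercept = y. Tabular learners see only the current
month's factors; sequence learners consume sliding 12-month windows and
need lookback context (≥ 11 preceding rows) when predicting beyond their
training matrix — without context the window is left-padded by replicating
the first row, which is exact once the window has rolled over. Inputs are
z-scored on the training window for SVR and the sequence learners; LR and
RF see raw units.

Per-model seeds are derived from the master seed and the model coordinates
via CRC-32, so sweeps are reproducible and individual models re-fittable in
isolation.

## Trend statistics

Monthly series are annualised (calendar-year means) before trend fitting;
slopes are therefore per year. Mann–Kendall uses the tie-corrected variance
and the ±1 continuity correction on Z; Sen's slope is the median of all
pairwise slopes (scipy's Theil–Sen implementation; an OLS slope is available
by flag). Greening means Sen's slope > 0; fractions are cosine-latitude
area-weighted percentages over vegetated cells with a defined trend. The
future-vs-historical rate change is reported both as a percentage,
100 · rate_future / rate_hist, and as a multiple, percent / 100 — i.e. the
multiple is the plain ratio, not ratio − 1 — matching how such tables are
conventionally read. A zero historical rate makes the ratio undefined and
raises.

## Preprocessing

Cubes are CF-style NetCDF (classic format via xarray's scipy backend),
cell-center registered, latitude ascending, longitude in [−180, 180),
missing values as NaN behind the file's fill value. Maximum-value
compositing takes the per-calendar-month maximum over unmasked values, a
cell being masked only when the whole month is masked; the same mask rule
applies to the monthly aggregation (totals for Pre, ET and the CO₂ proxy;
means for Tmp and SM). Bilinear regridding interpolates each time slice on
the source cell centers and is exact (to ~1e-13) for fields bilinear in
lat/lon; target points outside the source hull come back masked, and
longitude wrap is off by default. The default vegetation mask is
historical-mean LAI > 0.1 m² m⁻², a conventional low-LAI cutoff for
"vegetated area".

## The synthetic test bed

Each climate factor is a latitude-dependent climatology + hemisphere-phased
seasonal cycle + linear trend + AR(1) red noise (coefficient 0.3, enough
temporal memory to exercise the sequence learners). Scenario windows
continue the historical trend scaled by per-scenario multipliers
(1, 2, 3, 4 for the four scenarios), continuous at the 2014/2015 boundary.
Each pseudo-ESM observes this shared truth through its own additive bias and
extra AR(1) noise, so MME and DISO-W genuinely differ. Observed LAI is a
linear (optionally quadratic) link of the per-cell standardised generating
factors — {SM, CO₂} by default, configurable per latitude band — plus
Gaussian noise at 10 % of the signal SD, clipped at zero. The defaults are a
global 20 × 40 grid (9° spacing — coarse, but covering all latitude bands so
every region is populated), 396 historical months (1982–2014) and 1032
scenario months (2015–2100).

What passing tests show: the sweep machinery ranks, selects and projects
correctly, and recovers a known generating factor subset under realistic
noise. What they do not show: skill on real satellite LAI or CMIP6 climate,
whose spatial covariance, non-stationarities, observation errors and
saturation effects the generator deliberately does not emulate. Region-level
numbers computed on synthetic data (trend rates, greening fractions) are
properties of the generator, not of the Earth.

The ground-truth recovery study runs 20 seeded replicates of the
31-combination × 4-dataset grid with the two fast algorithm families
(LR, SVR) — the combination/dataset dimensions are where recovery lives —
plus one full six-algorithm 744-model sweep; this keeps the default test run
at desk scale.

## Known limitations

* Selection uses a single chronological split; no cross-validation schemes.
* The sequence learners train only their readout; they are representative
  members of their families at desk scale, not tuned deep networks, and will
  understate what heavily-trained networks can do.
* Mann–Kendall has no prewhitening; strongly autocorrelated annual series
  will overstate significance.
* Regridding is restricted to regular lat/lon grids; no satellite QA-flag
  handling or native-resolution (0.05°) product processing.
* DISO-W weights are computed from one reference factor combination per
  (region, algorithm); recomputing them per factor combination is a
  plausible alternative reading and is deliberately not the default.
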
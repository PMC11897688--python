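# laiproj

Optimal-model-combination projection of vegetation (leaf area index, LAI)
from climate factors.

## The problem

Projecting how global vegetation will respond to climate change is hard
because the answer is spatially heterogeneous three times over: different
regions respond to *different climate factors*, are better described by
*different climate datasets*, and are better fit by *different regression
algorithms*. A single model applied everywhere bakes in the wrong choice
somewhere. `laiproj` is a toolkit for researchers in ecological forecasting
and vegetation–climate modelling who want to make all three choices
empirically, per region, and then project forward under emission scenarios.

## The method

For each study region (the globe plus four latitude bands: 60–90° N,
30–60° N, 30° S–30° N, 30–60° S), the toolkit exhaustively crosses:

* the **31** nonempty subsets of five climate factors — evapotranspiration
  (ET), soil moisture (SM), precipitation (Pre), temperature (Tmp), and a
  CO₂ proxy (net biome production);
* **4** candidate climate datasets — two earth-system models plus two
  combinations of them: the equal-weight multi-model ensemble mean (MME) and
  an inverse-skill weighted combination (DISO-W, below);
* **6** regression algorithm families — linear regression, RBF support
  vector regression, random forest, and convolutional / recurrent /
  attention sequence learners;

giving 31 × 4 × 6 = **744** candidate models per region. Every candidate is
fit on the first 80 % of the historical monthly record and scored on the
held-out tail with the **DISO** composite skill metric: the Euclidean
distance of the indicator vector (R², norMAE, norRMSE) from the ideal point
(1, 0, 0),

```
DISO = sqrt((R² − 1)² + norMAE² + norRMSE²),
```

where MAE and RMSE are normalised by the mean absolute observation. Smaller
is better; 0 is a perfect simulation. Selection is hierarchical: the best
dataset per (factor subset, algorithm) → 186 models; the best algorithm per
factor subset → 31 models; the overall minimum-DISO model → the regional
optimum, which is refit on the full historical window and driven with
scenario climate (SSP1-2.6 … SSP5-8.5) to 2100.

The **DISO-W** dataset weights each candidate dataset *l* by its inverse
skill, `w_l = (1/DISO_l) / Σ_k (1/DISO_k)`, computed per (region, algorithm)
from a reference model fit, and applies the same weight to all five factors.

Trend analytics use the Mann–Kendall test (tie-corrected variance,
continuity-corrected Z) and Sen's slope, with cosine-latitude area weighting
for regional means and greening/browning fractions, per-period rates, and
future-vs-historical rate ratios.

A seeded synthetic-data module generates the full study structure — two
pseudo-ESM factor bundles with distinct bias and noise, historical
(1982–2014) and four scenario (2015–2100) windows with increasing trend
multipliers, LAI built from a *known* factor subset, daily LAI for
compositing tests and three pseudo-products at mixed resolutions — so every
stage, including ground-truth recovery by the sweep, is testable offline.

## Worked example

```python
import laiproj as lp
from laiproj.io_preprocess import extract_region_frame

cfg = lp.SynthConfig(seed=1)                      # synthetic study conditions
clim = lp.simulate_factor_bundles(cfg)            # two pseudo-ESMs + scenarios
lai, truth = lp.simulate_lai(clim)                # LAI = linear(SM, CO2) + 10% noise

region = lp.REGIONS_BY_NAME["Global"]
obs = lp.extract_region(lai, region)
esm = {b.dataset_id: extract_region_frame(b, region) for b in clim.historical}
scen = {s: {b.dataset_id: extract_region_frame(b, region) for b in bundles}
        for s, bundles in clim.scenarios.items()}

out = lp.run_region("Global", obs, esm, scenario_frames=scen, master_seed=1)
opt = out.selection.optimum
print(f"optimum: {'+'.join(opt.spec.combination.members)} | "
      f"{opt.spec.dataset_id} | {opt.spec.algorithm_id} | DISO={opt.score.value:.4f}")

ann = lp.annualize(obs)
hist_rate = lp.sen_slope(ann.to_numpy(), ann.index.to_numpy(float))
print(f"historical LAI trend: {hist_rate:.4f} m2 m-2 yr-1")
for scen_name, series in out.projections.items():
    a = lp.annualize(series)
    rate = lp.sen_slope(a.to_numpy(), a.index.to_numpy(float))
    ratio = lp.rate_ratio(hist_rate, rate)
    print(f"{scen_name}: trend {rate:.4f} m2 m-2 yr-1  "
          f"({ratio.times:.2f}x the historical rate)")
```

prints (about a minute on one CPU):

```
optimum: SM+Pre+Tmp+CO2 | DISO-W | LR | DISO=0.1756
historical LAI trend: 0.0947 m2 m-2 yr-1
SSP126: trend 0.0924 m2 m-2 yr-1  (0.98x the historical rate)
SSP245: trend 0.1844 m2 m-2 yr-1  (1.95x the historical rate)
SSP370: trend 0.2751 m2 m-2 yr-1  (2.90x the historical rate)
SSP585: trend 0.3674 m2 m-2 yr-1  (3.88x the historical rate)
```

The sweep finds a factor set containing the generating pair {SM, CO₂} (the
extra factors are cheap under a linear learner), picks the inverse-skill
weighted dataset and the linear algorithm — the correct family for a linear
truth — and the projected greening rate scales with scenario forcing, here
reaching ≈3.9× the historical rate under the strongest scenario.

The same pipeline is available from the shell:

```sh
laiproj synth --seed 1 --out data/
laiproj select --data-dir data/ --regions Global --scenarios SSP126,SSP585 --out run/
laiproj trends --series run/Global_SSP585_projection.csv --hist-rate 0.0947
```

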
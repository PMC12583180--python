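# vegdyn

Vegetation-cover dynamics for mountain basins: a tested, reusable Python
implementation of the standard remote-sensing analysis chain that takes a
gridded vegetation-index time series (e.g. monthly EVI composites at 250 m)
to fractional vegetation cover (FVC), per-pixel trend and stability
typologies, grade-transition accounting, terrain dominance analysis, and
driver attribution with the geodetector q statistic and PLS structural
equation modeling.

It is aimed at spatial ecologists and remote-sensing analysts who want the
whole chain as scriptable, unit-tested library calls rather than a GIS
click-path — and who want every statistical engine validated against
brute-force oracles and synthetic scenes with known ground truth.

## Methods at the core

* **Dimidiate pixel model.** Each pixel's index value is a linear mixture of
  a pure-soil and a pure-vegetation endmember:
  `FVC = (EVI − EVI_soil) / (EVI_veg − EVI_soil)`, clipped to [0, 1].
  Endmembers are the 0.5 % / 99.5 % cumulative-frequency percentiles of the
  unmasked EVI distribution. Monthly layers are maximum-value composites
  (MVC) of sub-monthly periods; annual EVI is the mean of monthly MVCs.
* **Trend typology.** Per pixel, the Theil–Sen slope
  `ρ = median[(x_j − x_i)/(j − i)]` and the Mann–Kendall statistic
  `S = ΣΣ sign(x_j − x_i)` with `Var(S) = n(n−1)(2n+5)/18` and the
  continuity-corrected normal statistic Z. Five classes from
  (ρ ≷ ±0.0005, |Z| ≷ 1.96): significant/insignificant improvement,
  stabilization, insignificant/significant degradation.
* **Stability.** Coefficient of variation `CV = s/x̄` (sample sd over mean),
  graded into five fluctuation classes at 0.07/0.17/0.30/0.50.
* **Transition accounting.** Class-by-class area matrices `s_ij` between
  epochs; net change, inflow/outflow shares, off-diagonal changed area,
  Sankey flow tables.
* **Terrain dominance.** `K = (S_ie/S_e)/(S_i/S)` per change type i and
  terrain stratum e (elevation belts, slope classes, aspect sectors);
  K > 1 marks dominance. Exact Fisher–Jenks natural breaks are available
  for data-driven stratification.
* **Geodetector.** `q = 1 − ΣN_hσ_h²/(Nσ²)` measures how much a
  stratification explains the spatial variance of FVC, with ANOVA-F
  significance and the five-type interaction detector on factor overlays.
* **PLS-SEM.** Reflective composite path modeling
  (`X = Λξ + δ`, `η = Bη + Γξ + ζ`): iterated outer weights
  (centroid/factor/path schemes), standardized path coefficients, R²,
  communality, AVE, `GOF = √(mean communality × mean R²)`, bootstrap
  significance, and direct/indirect/total effect decomposition.

A synthetic closed-basin scene generator (DEM with lapse-rate climate,
autocorrelated categorical land-use/soil fields, monthly EVI with planted
trends and driver couplings, recorded ground truth) makes the whole chain
testable without any downloads.

## Worked example

Re-deriving published basin statistics from a printed transition matrix
(the Qinghai Lake Basin 2001→2012 FVC grade matrix shipped with the
package):

```python
from vegdyn import datasets
from vegdyn.transitions import net_change, flow_shares, changed_area

tm = datasets.load_transition("2001", "2012")
print(f"low-coverage net change 2001-2012: {net_change(tm, 'low coverage'):.2f} km2")
for target, share in flow_shares(tm, "low coverage", "outflow").items():
    print(f"  outflow to {target}: {share:.2f}%")
full = datasets.load_transition("2001", "2022")
print(f"total inter-grade change 2001-2022: {changed_area(full):.2f} km2")
```

```
low-coverage net change 2001-2012: -1526.12 km2
  outflow to medium-low coverage: 66.14%
  outflow to medium coverage: 26.94%
  outflow to medium-high coverage: 5.89%
  outflow to high coverage: 1.04%
total inter-grade change 2001-2022: 10850.91 km2
```

Low-grade cover shrank by ~1526 km², two-thirds of the lost area moving up
one grade; 10 851 km² changed grade over the full period (the off-diagonal
sum of the printed matrix).

End to end on a synthetic scene with a planted +0.002/a trend block:

```python
from vegdyn import (SceneConfig, generate_scene, monthly_composite,
                    annual_mean_evi, GridStack, trend_analysis)
from vegdyn.transitions import grade_area_summary

cfg = SceneConfig(shape=(60, 60), years=(2001, 2022), seed=42)
scene = generate_scene(cfg)
monthly = monthly_composite(scene.evi_monthly)
annual = GridStack([annual_mean_evi(monthly, y) for y in cfg.year_list],
                   [(y,) for y in cfg.year_list])
res = trend_analysis(annual)
print(grade_area_summary(res.trend_class, cell_area_km2=0.0625).to_string(index=False))
tau = scene.truth["trend"].values
est = res.slope.values[tau == 0.002].mean() - res.slope.values[tau == 0].mean()
print(f"planted trend 0.0020/a, recovered {est:.4f}/a")
```

```
                    class  area_km2  percentage
  significant degradation   27.1250   12.055556
insignificant degradation   92.5625   41.138889
            stabilization   39.3750   17.500000
insignificant improvement   63.3125   28.138889
  significant improvement    2.6250    1.166667
planted trend 0.0020/a, recovered 0.0020/a
```

The scene's shared interannual climate signal happens to drift downward for
this seed, so absolute slopes shift and few pixels clear the significance
bar — differencing the planted block against the zero-trend region recovers
the planted 0.002/a exactly. The full chain (FVC → trend → transitions →
terrain → geodetector → PLS-SEM) also runs as one call:
`vegdyn run --seed 1 --outdir myrun` or `run_pipeline(PipelineConfig())`.

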
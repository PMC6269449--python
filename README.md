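# bnfcurve

Seasonal dynamics of biological nitrogen fixation (BNF) in soybean,
estimated from stem ureide assays and modelled on a thermal-time axis.

Soybean covers a large share of its nitrogen demand through symbiotic
fixation in root nodules, and fixed N is exported from the nodules as
ureides. The **relative abundance of ureides** in stem tissue,

```
RAU (%) = 100 · 4U / (4U + N)
```

with ureide concentration `U` and nitrate concentration `N` on any single
consistent unit basis, is therefore a field-practical proxy for the
fraction of plant N derived from fixation. Sampled at four phenological
stages (V4, R2, R6, R8) and placed on a cumulative thermal-time axis
(degree-days above 8 °C from the V2 stage), seasonal RAU follows a rise-
and-decline pattern described by the three-parameter **beta growth
function**

```
RAU(t) = RAU_max · (1 + (t_max − t)/(t_max − t_m)) · (t/t_max)^(t_max/(t_max − t_m))
```

where `RAU_max` is the peak, reached at `t_max`, and `t_m` is the thermal
time of the maximum rate. The package fits this curve per fixation group ×
N-fertilizer treatment, derives the maximum rate (closed form), `t_0.5`
(time to half the peak) and the area under the curve, compares treatment
curves with the small-sample AICc, and — after removing the phenology
trend in agronomic traits with a continuous bilinear model of thermal time
to R6 — regresses trait residuals on RAU at R6 at the mean and at the
0.99/0.01 quantile boundaries.

It is written for crop physiologists and agronomists analysing
multi-environment legume trials, and ships a synthetic trial-network
generator (sites × treatments × blocks, assays, weather, outcomes) so the
whole pipeline is testable without field data.

## Worked example

```python
import numpy as np
from bnfcurve import beta_rau, fit_beta

rng = np.random.default_rng(42)
true = (84.0, 362.0, 1066.0)                     # RAU_max %, t_m, t_max (°Cd)
tt_r6 = rng.uniform(909, 1330, 12)               # thermal time to R6, 12 sites
t = np.concatenate([f * tt_r6 for f in (0.2, 0.55, 1.0, 1.3)])
rau = beta_rau(t, true) + rng.normal(0, 12, t.size)

fit = fit_beta((t, rau))
print(f"RAU_max = {fit.rau_max:.1f} ± {fit.se_rau_max:.1f} %")
print(f"max rate = {fit.max_rate:.4f} % per °Cd, t_0.5 = {fit.t_half:.0f} °Cd")
print(f"R2 = {fit.r2:.2f}, Syx = {fit.syx:.1f} %")
```

prints

```
RAU_max = 84.7 ± 2.1 %
max rate = 0.1164 % per °Cd, t_0.5 = 424 °Cd
R2 = 0.89, Syx = 9.0 %
```

— the fit recovers the generating peak (84) within one standard error; the
maximum fixation rate of ~0.12 RAU points per degree-day and the half-rise
time of ~420 °Cd after V2 characterise when the crop's fixation machinery
ramps up. The `examples/` directory has one short script per capability
(RAU and thermal time, curve fitting, de-trending + quantile regression,
full pipeline); each prints the numbers it computes with a note on their
meaning.

A thin CLI wraps the same functions:

```sh
bnfcurve simulate --seed 1 --out-dir data/
bnfcurve pipeline --seed 1 --out-dir report/
```

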
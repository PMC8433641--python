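# siakit

Statistics for **stability-indicating assay (SIA) validation** and
**chemical degradation kinetics**, built for chromatographic peak tables.

When an analytical lab validates a quantitation method for a drug
substance — here motivated by an ester prodrug assayed by UPLC in buffer
solutions — the report reduces to a fixed set of statistical procedures
on integrated peak areas. `siakit` implements that set as a tested,
reusable library with a thin CLI:

* **System suitability** — %CV of replicate injections, USP tailing
  factor `T = W₀.₀₅ / 2f`, plate count `N = 5.54 (t_R / w½)²`,
  resolution `Rs = 2(t_R2 − t_R1)/(w₁ + w₂)`, with pass/fail limits
  (%CV < 2, T < 2, N > 2000, Rs > 2).
* **Linearity** — homoscedasticity F-test on the extreme calibration
  levels (`F = s²_high / s²_low` vs `F(1−α; n−1, n−1)`); weighted least
  squares with empirical weights `w = 1, 1/x, 1/x²` selected by the
  minimum summed absolute back-calculation relative error Σ|%RE|;
  lack-of-fit ANOVA against pure error; slope/intercept t-tests and the
  regression F; back-calculation table with ±20% (LOQ) / ±15% bands.
* **Sensitivity** — LOD/LOQ by signal-to-noise (S/N ≥ 3 and ≥ 10) with
  recovery (80–110%) and precision (%CV < 15) acceptance.
* **Accuracy / precision / robustness / solution stability / forced
  degradation** — %recovery, %CV and percent-remaining bookkeeping.
* **Degradation kinetics** — zero, pseudo-first and second-order rate
  laws fitted by linearisation (`C`, `ln C`, `1/C` vs `t`), order chosen
  by highest mean r² across replicates, rate constant `k_obs` and
  half-life (`t½ = ln 2 / k` for first order) averaged per replicate.
* **Synthetic data** — seeded generators for every input (heteroscedastic
  calibrations, decay time courses, suitability injections with synthetic
  peak shapes, blank traces), so the whole pipeline runs with no
  instrument data.

The calibration and kinetics cores follow the statsmodels idiom: a model
object built from data whose `fit()` returns a results object with
estimates, uncertainties, diagnostics and a `summary()` table.

## Worked example

```python
from siakit import (CalibrationSimSpec, DecaySimSpec, DegradationKinetics,
                    WeightedCalibration, gen_calibration, gen_decay,
                    select_weighting)

# 6-level (0.10–25 µg/mL) triplicate calibration with 2% proportional noise
data = gen_calibration(CalibrationSimSpec(seed=1))
homo = WeightedCalibration(data).homoscedasticity_test()
print(homo.f_cal, homo.f_crit)         # 87283.7  99.0  -> heteroscedastic

sel = select_weighting(data)
print(sel.summary())
#  weighting     slope  intercept        r       r2  sum_abs_re  chosen
#          1  7065.016   -211.544  0.999897  0.999794    82.315   False
#        1/x  7047.816    -62.188  0.999939  0.999878    14.549   False
#      1/x^2  7034.114    -55.080  0.999935  0.999871    14.249    True

# triplicate first-order decay, C0 = 5 µg/mL, k = 0.045 h⁻¹, 0–24 h
res = DegradationKinetics(gen_decay(DecaySimSpec(seed=1))).select_order()
print(res.summary())
# chosen_order  first       (r²: zero 0.9733, first 0.9967, second 0.9768)
# k_mean        0.044866 h⁻¹   k_sd  0.000369
# t_half_mean_h 15.45 h        t_half_sd_h 0.127
```

The variance ratio between the highest and lowest calibration levels
(87,284 ≫ 99, the 99% F quantile at 2 and 2 degrees of freedom) rejects
homoscedasticity, so a weighted fit is used; `1/x²` attains the smallest
Σ|%RE| (14.2) and is selected. The kinetics stage identifies first-order
decay by its mean r² (0.997) and recovers the generating rate constant
0.045 h⁻¹ within 0.3%, giving a half-life near `ln 2 / k ≈ 15.4 h`.

From the shell:

```bash
siakit simulate calibration --out cal.csv --seed 1
siakit linearity cal.csv
siakit all --seed 1 --format md --out report.md
```

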
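# tbars-kinetics

Kinetic shelf-life modelling of secondary lipid oxidation in raw ground
beef enriched with plant extracts.

Lipid oxidation is the main chemical route by which raw meat loses sensory
and nutritional quality during storage, and the TBARS index
(thiobarbituric acid reactive substances, reported as mg malondialdehyde
per kg meat or as percent of the day-0 value) is its standard
spectrophotometric measure. This package implements the full predictive
pipeline for TBARS in minced beef stored at 4–20 °C with one of 13
antioxidant spice/herb extracts (or none, the control):

1. **Primary model** — first-order kinetics per storage temperature:
   `TBARS(t) = TBARS₀·exp(k t)`, with the rate constant `k` (day⁻¹)
   estimated as the OLS slope of ln TBARS(%) on storage day, per
   (treatment, temperature, replicate) series, aggregated to mean ± SD.
2. **Secondary models** — temperature dependence of `k`:
   * Arrhenius, `k = k₀·exp(−Eₐ/(R T))`, fitted by linear regression of
     ln k on 1/T (T in kelvin, R = 8.314 J mol⁻¹ K⁻¹); the activation
     energy `Eₐ` (J/mol) quantifies temperature sensitivity.
   * Log-logistic, `k = m′·ln(1 + exp(c (T − T_c)))` (T in °C, m′ = 1),
     fitted by deterministic grid-initialized nonlinear least squares.
3. **Shelf-life prediction** — the integrated models
   `TBARS = 100·exp(k₀ e^(−Eₐ/RT)·t)` and
   `TBARS = 100·exp(ln(1+e^(c(T−T_c)))·t)` evaluated at arbitrary
   time–temperature pairs, with **external validation** at a held-out
   storage temperature (default 12 °C): adjusted R² of the
   observed-vs-predicted regression and RMSE on raw paired errors.
4. **MLR treatment comparison** — dummy-coded regression of ln TBARS(%)
   on day, temperature and 13 treatment indicators (control as reference);
   more negative coefficients mean stronger oxidation inhibition.
5. **MLP comparator** — a 16-input single-hidden-layer perceptron
   (day, temperature, 14 treatment indicators → TBARS%), trained by BFGS
   on a sum-of-squares error with a 2:1:1 train/validation/test split and
   best-of-20 architecture selection by validation error.

A synthetic-data generator reproduces the study design (14 arms,
triplicates, 4/8/12 °C for 13 days and 16/20 °C for 5 days, multiplicative
lognormal noise), so every stage is testable without any external data.
The published per-extract rate constants and antioxidant assay values ship
as packaged CSV fixtures.

## Worked example

```python
import tbars_kinetics as tk

# Arrhenius parameters recomputed from the published control rate constants
rates = tk.load_published_rate_constants()
sub = rates[rates.extract == "control"]
arr = tk.fit_arrhenius(list(zip(sub.temperature_k, sub.k_mean)), treatment="control")
print(f"Ea = {arr.ea:.0f} J/mol, k0 = {arr.k0:.3g} 1/day, R2 = {arr.r2:.4f}")

ll = tk.fit_log_logistic(list(zip(sub.temperature_k - 273, sub.k_mean)))
print(f"c = {ll.c:.4f} 1/degC, Tc = {ll.tc:.2f} degC")

# predicted TBARS after 5 days at the held-out 12 degC
print(f"TBARS(12 degC, day 5) = {float(tk.predict_tbars(arr, 12, 5, kelvin_offset=273)):.1f} %")

# external validation on a synthetic study-design dataset
ds = tk.simulate_dataset(tk.published_like_truth(seed=1), tk.StorageDesign())
report = tk.holdout_pipeline(ds, 12.0, "arrhenius")
print(f"holdout: n = {report.n}, adj R2 = {report.r2_adj:.4f}, RMSE = {report.rmse:.1f}")
```

prints

```
Ea = 60223 J/mol, k0 = 3.24e+10 1/day, R2 = 0.9973
c = 0.1094 1/degC, Tc = 21.73 degC
TBARS(12 degC, day 5) = 441.9 %
holdout: n = 588, adj R2 = 0.9971, RMSE = 43.9
```

The activation energy of ~60 kJ/mol says the control's oxidation rate
roughly quadruples between 4 and 20 °C; the log-logistic parameters
describe the same curve without an activation-energy concept. The holdout
report shows the model fitted at 4/8/16/20 °C predicting the unseen 12 °C
series almost perfectly on clean synthetic data with realistic noise.

A command-line driver wraps the same stages:

```sh
tbars-kinetics simulate --seed 1 --out tbars.csv
tbars-kinetics fit-secondary tbars.csv --out secondary.csv
tbars-kinetics validate tbars.csv --holdout-temp 12 --out validation.json
tbars-kinetics run --simulate --seed 1 --out-dir reports/
```

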
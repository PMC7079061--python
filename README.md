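# forestflow

Tools for quantifying how annual river flow changes in the decades after
forestation, while separating the effect of forest ageing from year-to-year
climate variability.

When non-forested land converts to forest, transpiration and interception
rise and annual river flow usually falls. Whether flow later *partially
recovers* as stands age is hard to establish from catchment records,
because wet and dry spells mimic (or mask) age trends. `forestflow`
implements the full analysis chain used in paired- and single-catchment
meta-analyses of this question:

1. **Calibration** — reconstruct the control flow `Q_C` (flow expected
   under the old land cover) for study designs that never calibrated one,
   from pre-forestation regressions of flow on precipitation or on a twin
   catchment's flow, with strict acceptance gates (slope p < .05, adjusted
   R² > .5, residual normality) and no extrapolation beyond the calibrated
   predictor range.
2. **Preprocessing** — the flow response `Q_i = Q_Fi − Q_Ci` (mm; negative
   = reduction), area-weighted forest age for staggered plantings, and the
   split of precipitation/PET/forest cover into catchment means (`MAP`,
   mean `PET`, `FC_S`) plus within-catchment anomalies (`P_T`, `PET_T`,
   `FC_T`).
3. **Per-catchment curves** — through-origin least squares of `Q` on a
   linear, second-order polynomial or asymptotic `h(1 − e^{−e^k · Age})`
   function of forest age plus climate terms, selected by AIC with backward
   elimination, a |r| > .7 collinearity rule, and asymptotic preference
   when ΔAIC < 2; responses classified as negative, recovering-negative,
   positive or none.
4. **Hierarchical mixed model** — across all catchments,

       Q_i = a_j·Age + b_j·Age² + c_j·P_T + d_j·PET_T + ε,
       a_j ~ N(e + f·MAP + g·FC_S + h·MAP·FC_S + k_HF + l_PLU, σ₁²)
       b_j ~ N(m, σ₂²),  c_j ~ N(n + o·Aridity, σ₃²),  d_j ~ N(r + s·Aridity, σ₄²)

   with a freely correlated 4×4 random-effect covariance and AR(3) errors
   within catchments, estimated by profiled REML (or ML); marginal ANOVA
   and population-level predictions included. `HF` is historical forest
   presence, `PLU` prior land use, `Aridity = MAP / mean PET`.
5. **Recovery detection** — minimum-flow age `−a/2b`, confidence in the
   rebound (disjoint 95% CIs at the minimum vs the final age), the
   standardised 5-year recovery rate, climate-confounding screens, and
   Fisher / Kruskal–Wallis group tests — after excluding years with zero
   forested flow.
6. **Synthetic data** — a seeded generator producing catchment panels with
   exactly this statistical structure (plus raw flows with a
   pre-forestation calibration period), so the whole pipeline is testable
   end to end and parameter recovery can be demonstrated.

## Worked example

`examples/fit_hierarchical_model.py` simulates 80 catchments × 20 years at
the model's headline coefficients and refits them:

```
n = 1600 catchment-years across 80 catchments
REML loglik = -8425.9, AIC = 16905.7

fixed effects (truth in brackets):
  age                   -4.0195  (SE 2.38) [-5.3]
  age:map:fc_s       -0.0001325  (SE 2.62e-05) [-0.00015]
  age_sq                 +0.145  (SE 0.0412) [+0.18]
  p_t                 +0.015825  (SE 0.0225) [+0.015]
  p_t:aridity         -0.067532  (SE 0.0161) [-0.07]
  ...
random-effect SDs (age, age^2, P_T, PET_T): [7.018 0.174 0.082 0.46 ]
AR coefficients: [0.304 0.136 0.049]  residual SD: 45.7 mm
```

Every estimate lands within about one standard error of the generating
value; `age:map:fc_s < 0` says flow declines faster with age where both
rainfall and forest cover are high, and `p_t:aridity < 0` says wetter
catchments are more sensitive to wet years. The other example scripts
(`simulate_dataset.py`, `calibrate_control_flow.py`,
`fit_catchment_curves.py`, `detect_recovery.py`) each exercise one stage
the same way; e.g. `detect_recovery.py` prints

```
estimated minimum-flow age: 14.2 years
strong evidence for recovery (disjoint CIs): True
recovery over 5 years after the minimum: 22.7 mm
```

## Command line

The same stages are available as a thin CLI for running from CSV files:

```bash
forestflow simulate --seed 11 --out-dir sim/
forestflow calibrate --meta sim/catchments.csv --annual sim/annual.csv --out cal.csv
forestflow preprocess --meta sim/catchments.csv --annual cal.csv --out resp.csv
forestflow fit-catchments --responses resp.csv --out fits.csv
forestflow fit-hierarchical --responses resp.csv --meta sim/catchments.csv --out hier.json
forestflow recovery --responses resp.csv --out recovery.csv
forestflow run-all --work-dir run/ --seed 11 --simulate
```

Input schemas (`catchments.csv`, `annual.csv`) are documented in
`forestflow.data_model`.

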
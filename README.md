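# endopredict

Clinical prediction models for **pain reduction after laparoscopic
endometriosis surgery**, packaged as a reusable, tested Python pipeline.

About one woman in four does not experience pain relief after therapeutic
laparoscopy for endometriosis, yet prognosis is rarely discussed before
surgery. Published models predict, from patient characteristics and
intraoperative findings, the probability of a clinically meaningful
improvement at 6 months in five domains: dysmenorrhoea, dyspareunia,
non-cyclical pelvic pain (NPP), dyschezia, and quality of life (QoL).
`endopredict` implements the full statistical workflow behind such models and
ships the eight published models as machine-readable **model cards**. The
patient-level registry data are not public, so a seeded synthetic-cohort
generator reproduces the data *structure* and lets every stage be exercised
and tested end to end.

## The methodology

* **Outcomes.** Pain scores (VAS 0–10) are dichotomized: a relative reduction
  of at least 30% from baseline counts as *improved*; for QoL (0–100), an
  absolute gain of at least 10 points. Baseline-zero VAS records (undefined
  relative reduction) are excluded with a logged count.
* **Development.** Logistic regression with the baseline score mandatory.
  Continuous predictors may enter through a first-degree fractional polynomial
  `((x+a)/s)^p − c`, `p ∈ {−2, −1, −0.5, 0(=log), 0.5, 1, 2, 3}`, chosen by a
  closed deviance test. Predictors are then selected by backward elimination
  on likelihood-ratio tests at **α = 0.157** (a proxy for best-subset
  selection by AIC), categorical variables as whole blocks.
* **Internal validation.** Bootstrap resampling (B = 200) with full replay of
  the selection procedure gives the optimism in the C-statistic, calibration
  slope and calibration-in-the-large (CITL). The optimism-adjusted slope is
  the **uniform shrinkage factor** S: final coefficients are `S·β̂` with the
  intercept re-estimated by maximum likelihood against the shrunken linear
  predictor as an offset.
* **External validation.** A frozen card is scored on a new cohort without
  refitting; C, slope, CITL and a decile calibration curve are reported.
* **Decision-curve analysis.** Net benefit
  `NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t)` across thresholds 0–0.80, against
  treat-all and treat-none.
* **Sample size.** The three standard minimum-n criteria for binary-outcome
  prediction models (target shrinkage, R² optimism, prevalence precision).

## Worked example

```python
import endopredict as ep

card = ep.load_shipped_card("dyspareunia_external")          # published model
cohort = ep.generate(ep.GeneratorSpec(n=2000, seed=19, truth=card))

dev = ep.DevelopmentSpec(candidates=(
    "strong_painkillers", "conceiving", "ovarian_usl_endo", "age", "smoking"))
res = ep.bootstrap_validate(cohort, dev, ep.ValidationSpec(B=200, seed=1))

print(res.apparent.c_statistic)   # 0.631
print(res.adjusted)               # {'c_statistic': 0.6198,
                                  #  'calibration_slope': 0.9144, 'citl': -0.0024}
print(res.shrinkage)              # 0.914
```

The apparent C-statistic of 0.631 says the freshly developed model separates
improvers from non-improvers somewhat better than chance on its own data; the
optimism-adjusted slope of 0.914 estimates how much its coefficients overfit
(ideal 1), and doubles as the shrinkage factor applied to the final card. The
`examples/` directory has one short script per capability: cohort simulation,
model development, internal validation, external validation with decision
curves, and sample size.

## Shipped model cards

`ep.list_shipped_cards()` returns eight cards transcribed from the published
development table: three models restricted to the predictors available for
external validation (`dysmenorrhoea_external`, `dyspareunia_external`,
`npp_external`) and five full-candidate models (`*_full` for those outcomes
plus `dyschezia_full` and `qol_full`). Coefficients are natural logs of the
printed odds ratios; transformations, centering constants, intercepts and
optimism-adjusted performance are stored verbatim, with rounding provenance
and label-direction caveats in each card's `notes`.

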
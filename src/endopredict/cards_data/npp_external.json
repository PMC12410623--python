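{
 "schema_version": 1,
 "name": "npp_external",
 "validation_scope": "external",
 "outcome": "npp",
 "scale": "vas",
 "n": 4263,
 "events": 2358,
 "intercept": {
  "value": 0.15,
  "se": 0.13
 },
 "terms": [
  {
   "name": "baseline_score",
   "kind": "continuous",
   "transform": {
    "shift": 1.0,
    "scale": 10.0,
    "power": -2.0,
    "center": 2.51
   },
   "or": 0.93,
   "ci": [
    0.92,
    0.95
   ],
   "coef": null,
   "se": null,
   "or_scale": "per unit of the transformed variable"
  },
  {
   "name": "strong_painkillers",
   "kind": "binary",
   "or": 0.86,
   "ci": [
    0.74,
    1.01
   ],
   "coef": null,
   "se": null
  },
  {
   "name": "conceiving",
   "kind": "categorical",
   "reference": "not_trying",
   "levels": [
    {
     "level": "trying_lt18m",
     "or": 1.58,
     "ci": [
      1.2,
      2.09
     ],
     "coef": null,
     "se": null
    },
    {
     "level": "trying_ge18m",
     "or": 1.06,
     "ci": [
      0.88,
      1.28
     ],
     "coef": null,
     "se": null
    }
   ]
  },
  {
   "name": "ovarian_usl_endo",
   "kind": "binary",
   "or": 1.76,
   "ci": [
    1.37,
    2.26
   ],
   "coef": null,
   "se": null
  },
  {
   "name": "age",
   "kind": "continuous",
   "transform": {
    "shift": 0.0,
    "scale": 1.0,
    "power": 1.0,
    "center": 35.09
   },
   "or": 1.04,
   "ci": [
    1.03,
    1.05
   ],
   "coef": null,
   "se": null,
   "or_scale": "per unit of the transformed variable"
  }
 ],
 "performance": {
  "optimism_adjusted": {
   "c_statistic": 0.741,
   "calibration_slope": 0.968,
   "citl": -0.001
  }
 },
 "shrinkage": null,
 "odds_ratios": {},
 "notes": {
  "source": "published development table, transcribed",
  "coefficients": "natural logs of the printed odds ratios (2 decimal places; wider CIs as printed)",
  "intercept": "printed to 2 decimal places with its standard error",
  "contrast_label_order": "reference vs level",
  "contrast_ambiguity": "printed contrast labels name the reference level first; the odds ratio is read as belonging to the second-named level relative to the first, matching the direction described in the study abstract; not silently inverted",
  "or_scale": "odds ratios for transformed continuous terms are per unit of the transformed variable"
 }
}
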
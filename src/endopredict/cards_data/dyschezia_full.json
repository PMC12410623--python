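{
 "schema_version": 1,
 "name": "dyschezia_full",
 "validation_scope": "internal_only",
 "outcome": "dyschezia",
 "scale": "vas",
 "n": 3272,
 "events": 1627,
 "intercept": {
  "value": 0.02,
  "se": 0.19
 },
 "terms": [
  {
   "name": "baseline_score",
   "kind": "continuous",
   "transform": {
    "shift": 1.0,
    "scale": 10.0,
    "power": -2.0,
    "center": 2.67
   },
   "or": 0.94,
   "ci": [
    0.93,
    0.95
   ],
   "coef": null,
   "se": null,
   "or_scale": "per unit of the transformed variable"
  },
  {
   "name": "strong_painkillers",
   "kind": "binary",
   "or": 0.63,
   "ci": [
    0.52,
    0.76
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
     "or": 1.57,
     "ci": [
      1.13,
      2.18
     ],
     "coef": null,
     "se": null
    },
    {
     "level": "trying_ge18m",
     "or": 1.12,
     "ci": [
      0.9,
      1.4
     ],
     "coef": null,
     "se": null
    }
   ]
  },
  {
   "name": "ovarian_usl_endo",
   "kind": "binary",
   "or": 1.45,
   "ci": [
    1.05,
    2.01
   ],
   "coef": null,
   "se": null
  },
  {
   "name": "hysterectomy",
   "kind": "binary",
   "or": 1.77,
   "ci": [
    1.28,
    2.46
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
    "center": 34.16
   },
   "or": 1.03,
   "ci": [
    1.01,
    1.04
   ],
   "coef": null,
   "se": null,
   "or_scale": "per unit of the transformed variable"
  },
  {
   "name": "bmi",
   "kind": "continuous",
   "transform": {
    "shift": 0.0,
    "scale": 1.0,
    "power": 1.0,
    "center": 25.79
   },
   "or": 0.98,
   "ci": [
    0.96,
    1.0
   ],
   "coef": null,
   "se": null,
   "or_scale": "per unit of the transformed variable"
  },
  {
   "name": "smoking",
   "kind": "categorical",
   "reference": "smoker",
   "levels": [
    {
     "level": "ex_smoker",
     "or": 1.17,
     "ci": [
      0.86,
      1.6
     ],
     "coef": null,
     "se": null
    },
    {
     "level": "never_smoker",
     "or": 1.33,
     "ci": [
      1.04,
      1.71
     ],
     "coef": null,
     "se": null
    }
   ]
  },
  {
   "name": "oocds",
   "kind": "binary",
   "or": 1.3,
   "ci": [
    1.08,
    1.56
   ],
   "coef": null,
   "se": null
  }
 ],
 "performance": {
  "optimism_adjusted": {
   "c_statistic": 0.808,
   "calibration_slope": 0.952,
   "citl": -0.002
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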
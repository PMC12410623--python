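{
 "schema_version": 1,
 "name": "dysmenorrhoea_full",
 "validation_scope": "internal_only",
 "outcome": "dysmenorrhoea",
 "scale": "vas",
 "n": 3056,
 "events": 1737,
 "intercept": {
  "value": -0.54,
  "se": 0.19
 },
 "terms": [
  {
   "name": "baseline_score",
   "kind": "continuous",
   "transform": {
    "shift": 1.0,
    "scale": 10.0,
    "power": -1.0,
    "center": 1.1
   },
   "or": 0.6,
   "ci": [
    0.54,
    0.68
   ],
   "coef": null,
   "se": null,
   "or_scale": "per unit of the transformed variable"
  },
  {
   "name": "strong_painkillers",
   "kind": "binary",
   "or": 0.69,
   "ci": [
    0.57,
    0.82
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
     "or": 1.67,
     "ci": [
      1.27,
      2.19
     ],
     "coef": null,
     "se": null
    },
    {
     "level": "trying_ge18m",
     "or": 1.0,
     "ci": [
      0.83,
      1.21
     ],
     "coef": null,
     "se": null
    }
   ]
  },
  {
   "name": "ovarian_usl_endo",
   "kind": "binary",
   "or": 1.59,
   "ci": [
    1.19,
    2.14
   ],
   "coef": null,
   "se": null
  },
  {
   "name": "hysterectomy",
   "kind": "binary",
   "or": 1.77,
   "ci": [
    1.29,
    2.44
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
    "center": 33.76
   },
   "or": 1.03,
   "ci": [
    1.02,
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
    "center": 25.64
   },
   "or": 0.98,
   "ci": [
    0.97,
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
     "or": 1.28,
     "ci": [
      0.97,
      1.68
     ],
     "coef": null,
     "se": null
    },
    {
     "level": "never_smoker",
     "or": 1.5,
     "ci": [
      1.2,
      1.87
     ],
     "coef": null,
     "se": null
    }
   ]
  },
  {
   "name": "oocds",
   "kind": "binary",
   "or": 1.49,
   "ci": [
    1.24,
    1.78
   ],
   "coef": null,
   "se": null
  },
  {
   "name": "hormonal_contraception",
   "kind": "binary",
   "or": 1.23,
   "ci": [
    1.03,
    1.46
   ],
   "coef": null,
   "se": null
  },
  {
   "name": "bowel_deep_endo",
   "kind": "binary",
   "or": 0.83,
   "ci": [
    0.68,
    1.02
   ],
   "coef": null,
   "se": null
  }
 ],
 "performance": {
  "optimism_adjusted": {
   "c_statistic": 0.651,
   "calibration_slope": 0.92,
   "citl": 0.004
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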
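{
 "schema_version": 1,
 "name": "qol_full",
 "validation_scope": "internal_only",
 "outcome": "qol",
 "scale": "qol",
 "n": 4255,
 "events": 2634,
 "intercept": {
  "value": 0.41,
  "se": 0.17
 },
 "terms": [
  {
   "name": "baseline_score",
   "kind": "continuous",
   "transform": {
    "shift": 1.0,
    "scale": 100.0,
    "power": 3.0,
    "center": 0.17
   },
   "or": 0.01,
   "ci": [
    0.003,
    0.01
   ],
   "coef": null,
   "se": null,
   "or_scale": "per unit of the transformed variable"
  },
  {
   "name": "strong_painkillers",
   "kind": "binary",
   "or": 0.67,
   "ci": [
    0.56,
    0.79
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
     "or": 1.78,
     "ci": [
      1.34,
      2.36
     ],
     "coef": null,
     "se": null
    },
    {
     "level": "trying_ge18m",
     "or": 1.22,
     "ci": [
      1.0,
      1.49
     ],
     "coef": null,
     "se": null
    }
   ]
  },
  {
   "name": "ovarian_usl_endo",
   "kind": "binary",
   "or": 1.3,
   "ci": [
    0.99,
    1.7
   ],
   "coef": null,
   "se": null
  },
  {
   "name": "hysterectomy",
   "kind": "binary",
   "or": 1.57,
   "ci": [
    1.3,
    1.9
   ],
   "coef": null,
   "se": null
  },
  {
   "name": "bmi",
   "kind": "continuous",
   "transform": {
    "shift": 0.0,
    "scale": 1.0,
    "power": 1.0,
    "center": 26.18
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
     "or": 1.18,
     "ci": [
      0.9,
      1.55
     ],
     "coef": null,
     "se": null
    },
    {
     "level": "never_smoker",
     "or": 1.27,
     "ci": [
      1.02,
      1.59
     ],
     "coef": null,
     "se": null
    }
   ]
  },
  {
   "name": "oocds",
   "kind": "binary",
   "or": 1.19,
   "ci": [
    1.01,
    1.9
   ],
   "coef": null,
   "se": null
  }
 ],
 "performance": {
  "optimism_adjusted": {
   "c_statistic": 0.792,
   "calibration_slope": 0.978,
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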
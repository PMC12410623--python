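{
 "schema_version": 1,
 "name": "dyspareunia_full",
 "validation_scope": "internal_only",
 "outcome": "dyspareunia",
 "scale": "vas",
 "n": 3632,
 "events": 1923,
 "intercept": {
  "value": -0.21,
  "se": 0.17
 },
 "terms": [
  {
   "name": "baseline_score",
   "kind": "continuous",
   "transform": {
    "shift": 1.0,
    "scale": 10.0,
    "power": -2.0,
    "center": 2.77
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
   "or": 0.77,
   "ci": [
    0.65,
    0.92
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
     "or": 1.51,
     "ci": [
      1.12,
      2.02
     ],
     "coef": null,
     "se": null
    },
    {
     "level": "trying_ge18m",
     "or": 1.24,
     "ci": [
      1.01,
      1.53
     ],
     "coef": null,
     "se": null
    }
   ]
  },
  {
   "name": "ovarian_usl_endo",
   "kind": "binary",
   "or": 1.85,
   "ci": [
    1.41,
    2.42
   ],
   "coef": null,
   "se": null
  },
  {
   "name": "hysterectomy",
   "kind": "binary",
   "or": 1.7,
   "ci": [
    1.34,
    2.15
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
    "center": 34.9879
   },
   "or": 1.02,
   "ci": [
    1.0,
    1.03
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
     "or": 1.32,
     "ci": [
      1.0,
      1.74
     ],
     "coef": null,
     "se": null
    },
    {
     "level": "never_smoker",
     "or": 1.4,
     "ci": [
      1.12,
      1.76
     ],
     "coef": null,
     "se": null
    }
   ]
  }
 ],
 "performance": {
  "optimism_adjusted": {
   "c_statistic": 0.768,
   "calibration_slope": 0.961,
   "citl": 0.005
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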
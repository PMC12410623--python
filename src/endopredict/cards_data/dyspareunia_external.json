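{
 "schema_version": 1,
 "name": "dyspareunia_external",
 "validation_scope": "external",
 "outcome": "dyspareunia",
 "scale": "vas",
 "n": 3636,
 "events": 1925,
 "intercept": {
  "value": -0.1,
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
    0.94,
    0.95
   ],
   "coef": null,
   "se": null,
   "or_scale": "per unit of the transformed variable"
  },
  {
   "name": "strong_painkillers",
   "kind": "binary",
   "or": 0.78,
   "ci": [
    0.66,
    0.93
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
     "or": 1.41,
     "ci": [
      1.05,
      1.89
     ],
     "coef": null,
     "se": null
    },
    {
     "level": "trying_ge18m",
     "or": 1.13,
     "ci": [
      0.92,
      1.38
     ],
     "coef": null,
     "se": null
    }
   ]
  },
  {
   "name": "ovarian_usl_endo",
   "kind": "binary",
   "or": 1.88,
   "ci": [
    1.43,
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
    "center": 35.0
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
   "name": "smoking",
   "kind": "categorical",
   "reference": "smoker",
   "levels": [
    {
     "level": "ex_smoker",
     "or": 1.34,
     "ci": [
      1.02,
      1.76
     ],
     "coef": null,
     "se": null
    },
    {
     "level": "never_smoker",
     "or": 1.39,
     "ci": [
      1.11,
      1.74
     ],
     "coef": null,
     "se": null
    }
   ]
  }
 ],
 "performance": {
  "optimism_adjusted": {
   "c_statistic": 0.759,
   "calibration_slope": 0.961,
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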
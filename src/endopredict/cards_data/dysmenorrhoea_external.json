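{
 "schema_version": 1,
 "name": "dysmenorrhoea_external",
 "validation_scope": "external",
 "outcome": "dysmenorrhoea",
 "scale": "vas",
 "n": 3058,
 "events": 1738,
 "intercept": {
  "value": -0.49,
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
   "or": 0.61,
   "ci": [
    0.54,
    0.69
   ],
   "coef": null,
   "se": null,
   "or_scale": "per unit of the transformed variable"
  },
  {
   "name": "strong_painkillers",
   "kind": "binary",
   "or": 0.68,
   "ci": [
    0.57,
    0.81
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
     "or": 1.61,
     "ci": [
      1.23,
      2.12
     ],
     "coef": null,
     "se": null
    },
    {
     "level": "trying_ge18m",
     "or": 0.97,
     "ci": [
      0.8,
      1.17
     ],
     "coef": null,
     "se": null
    }
   ]
  },
  {
   "name": "ovarian_usl_endo",
   "kind": "binary",
   "or": 1.61,
   "ci": [
    1.2,
    2.16
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
    "center": 33.77
   },
   "or": 1.04,
   "ci": [
    1.02,
    1.05
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
     "or": 1.26,
     "ci": [
      0.96,
      1.67
     ],
     "coef": null,
     "se": null
    },
    {
     "level": "never_smoker",
     "or": 1.48,
     "ci": [
      1.19,
      1.85
     ],
     "coef": null,
     "se": null
    }
   ]
  },
  {
   "name": "oocds",
   "kind": "binary",
   "or": 1.48,
   "ci": [
    1.24,
    1.77
   ],
   "coef": null,
   "se": null
  },
  {
   "name": "hormonal_contraception",
   "kind": "binary",
   "or": 1.22,
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
    1.01
   ],
   "coef": null,
   "se": null
  }
 ],
 "performance": {
  "optimism_adjusted": {
   "c_statistic": 0.646,
   "calibration_slope": 0.934,
   "citl": 0.0
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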
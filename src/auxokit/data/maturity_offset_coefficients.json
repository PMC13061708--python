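{
  "_source": "Sex-specific maturity-offset interaction-term regressions of Mirwald, Baxter-Jones, Bailey & Beunen (2002), Med Sci Sports Exerc 34(4):689-694. Transcribed 2026-09-28 and verified by term-by-term hand evaluation of worked examples.",
  "_predictors": {
    "intercept": "1",
    "ll_x_sh": "leg length (cm) x sitting height (cm)",
    "age_x_ll": "decimal age (yr) x leg length (cm)",
    "age_x_sh": "decimal age (yr) x sitting height (cm)",
    "age_x_wt": "decimal age (yr) x weight (kg)",
    "wt_by_ht": "weight (kg) / standing height (cm) x 100"
  },
  "male": {
    "intercept": -9.236,
    "ll_x_sh": 0.0002708,
    "age_x_ll": -0.001663,
    "age_x_sh": 0.007216,
    "age_x_wt": 0.0,
    "wt_by_ht": 0.02292
  },
  "female": {
    "intercept": -9.376,
    "ll_x_sh": 0.0001882,
    "age_x_ll": 0.0022,
    "age_x_sh": 0.005841,
    "age_x_wt": -0.002658,
    "wt_by_ht": 0.07693
  }
}
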
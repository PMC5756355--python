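{
  "name": "china_crc_2012",
  "exposure_table": "exposures.csv",
  "burden_table": "burden.csv",
  "urban_weight": 0.3333333333333333,
  "z": 1.96,
  "rounding": {
    "enabled": true,
    "paf_decimals": 3
  },
  "factors": [
    {
      "name": "tobacco_smoking",
      "kind": "binary",
      "direction": "harmful"
    },
    {
      "name": "alcohol_drinking",
      "kind": "binary",
      "direction": "harmful"
    },
    {
      "name": "overweight_obesity",
      "kind": "multi_level",
      "direction": "harmful"
    },
    {
      "name": "physical_inactivity",
      "kind": "binary",
      "direction": "harmful"
    },
    {
      "name": "low_vegetable_intake",
      "kind": "quantile_dose_response",
      "direction": "protective"
    },
    {
      "name": "low_fruit_intake",
      "kind": "quantile_dose_response",
      "direction": "protective"
    },
    {
      "name": "high_red_processed_meat",
      "kind": "quantile_dose_response",
      "direction": "harmful"
    }
  ]
}
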
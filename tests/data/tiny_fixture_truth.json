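{
  "_comment": "Hand-enumerated truth for the 10-person fixture (study year 2012). Sets are post-exclusion; profile values computed by hand/spreadsheet from the fixture rows.",
  "sets": {
    "A": ["b01"],
    "B_psy_1y": ["b03"],
    "B_gen_principal_1y": ["b07"],
    "B_psy_2y": ["b03", "b04"],
    "B_gen_principal_2y": ["b07"],
    "C_psy_history": ["b05"],
    "C_gen_principal_history": ["b07"],
    "D_1y": ["b08"],
    "D_2y": ["b08"],
    "E": ["b09"],
    "excluded_bipolar": ["b10"]
  },
  "antidepressant_users": ["b01", "b05", "b06", "b07", "b09"],
  "denominator_count": 10,
  "table_rows": {"beneficiaries": 10, "ald_episodes": 2, "hospital_stays": 9, "dispensings": 31},
  "full_population_profile": {
    "n": 10,
    "age_mean": 49.0,
    "age_sd": 18.29207478663916,
    "age_iqr_low": 32.0,
    "age_iqr_high": 64.0,
    "pct_male": 50.0,
    "pct_antidepressant": 50.0,
    "pct_anxiolytic": 10.0,
    "pct_neuroleptic": 10.0,
    "pct_hypnotic": 10.0,
    "pct_any_psychotropic": 70.0,
    "mortality_pct": 10.0,
    "cmuc_pct_under60": 50.0,
    "comorbidity_pcts": {
      "cardiovascular": 10.0,
      "diabetes": 10.0,
      "cancer": 10.0,
      "neurological": 10.0,
      "inflammatory_hiv": 0.0,
      "eskd": 0.0,
      "liver_pancreas": 0.0
    },
    "cost_totals": {
      "ambulatory": 946.0,
      "pharma": 624.0,
      "hospital": 3697.0,
      "sick_leave": 435.0,
      "disability": 581.0,
      "total": 6283.0
    }
  }
}
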
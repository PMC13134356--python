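{
  "comment": "Default adult (>=20y) cardiovascular-health scoring rubric in the Life's Essential 8 style. Numeric bands are [low, high, points]: low inclusive, high exclusive, null = unbounded. Blood pressure scores as the minimum of the systolic and diastolic band points. Medication penalties subtract from the band score with a floor of 0. Diet cutpoints are percentile anchors (25/50/75/95th) of a DASH 0-80 adherence score.",
  "bmi": {
    "input": "bmi",
    "bands": [[null, 25.0, 100], [25.0, 30.0, 70], [30.0, 35.0, 30], [35.0, 40.0, 15], [40.0, null, 0]]
  },
  "lipid": {
    "input": "non_hdl_mgdl",
    "bands": [[null, 130.0, 100], [130.0, 160.0, 60], [160.0, 190.0, 40], [190.0, 220.0, 20], [220.0, null, 0]],
    "medication": "lipid_med",
    "med_penalty": 20
  },
  "glucose": {
    "fbg_input": "fasting_glucose_mgdl",
    "hba1c_input": "hba1c_pct",
    "medication": "glucose_med",
    "diabetes_if": {"fbg_at_least": 126.0, "hba1c_at_least": 6.5},
    "nondiabetic_fbg_bands": [[null, 100.0, 100], [100.0, 126.0, 60], [126.0, null, 40]],
    "nondiabetic_hba1c_bands": [[null, 5.7, 100], [5.7, 6.5, 60], [6.5, null, 40]],
    "diabetic_hba1c_bands": [[null, 7.0, 40], [7.0, 8.0, 30], [8.0, 9.0, 20], [9.0, 10.0, 10], [10.0, null, 0]]
  },
  "bp": {
    "sbp_input": "sbp_mmhg",
    "dbp_input": "dbp_mmhg",
    "sbp_bands": [[null, 120.0, 100], [120.0, 130.0, 75], [130.0, 140.0, 50], [140.0, 160.0, 25], [160.0, null, 0]],
    "dbp_bands": [[null, 80.0, 100], [80.0, 90.0, 50], [90.0, 100.0, 25], [100.0, null, 0]],
    "medication": "bp_med",
    "med_penalty": 20
  },
  "diet": {
    "input": "diet_score",
    "bands": [[null, 29.6, 0], [29.6, 35.0, 25], [35.0, 40.4, 50], [40.4, 48.2, 80], [48.2, null, 100]]
  },
  "pa": {
    "input": "pa_minutes",
    "bands": [[null, 1.0, 0], [1.0, 30.0, 20], [30.0, 60.0, 40], [60.0, 90.0, 60], [90.0, 120.0, 80], [120.0, 150.0, 90], [150.0, null, 100]]
  },
  "nicotine": {
    "input": "nicotine_status",
    "categories": {"never": 100, "quit_5y+": 75, "quit_1_5y": 50, "quit_<1y": 25, "current": 0}
  },
  "sleep": {
    "input": "sleep_hours",
    "bands": [[null, 4.0, 0], [4.0, 5.0, 20], [5.0, 6.0, 40], [6.0, 7.0, 70], [7.0, 9.0, 100], [9.0, 10.0, 90], [10.0, null, 40]]
  }
}
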
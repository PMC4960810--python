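{
  "config_version": "1.0",
  "seed": 20160725,
  "study": {
    "dose_mg_per_kg": 3.3,
    "sampling_times_h": [0.08333333333333333, 0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 12.0, 24.0],
    "n_subjects": 4,
    "arms": ["transfected", "naive"],
    "seed": 20160725
  },
  "pk": {"cl": 17.7, "v1": 23.4, "q": 22.9, "v2": 58.1},
  "pd": {"t0": 100.0, "kg": 0.25, "imax": 1.5, "ic50": 15.0},
  "link": {"k_in": 2.7, "k_out": 4.0},
  "noise": {"conc_cv": 0.3, "count_cv": 0.2, "burden_cv": 0.15, "lloq": 1.0},
  "regimens": [
    {"label": "3.3 mg/kg x3 daily", "events": [[0.0, 3.3], [24.0, 3.3], [48.0, 3.3]]},
    {"label": "10 mg/kg x3 daily", "events": [[0.0, 10.0], [24.0, 10.0], [48.0, 10.0]]},
    {"label": "20 mg/kg x3 daily", "events": [[0.0, 20.0], [24.0, 20.0], [48.0, 20.0]]}
  ],
  "growth_days": [0.0, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0],
  "n_growth_subjects": 5,
  "horizon_day": 21.0,
  "molar_mass_g_mol": null,
  "imaging_background_counts_per_s": 5000.0,
  "standard_slope_counts_per_uM": 100000.0,
  "standard_intercept_counts": 0.0
}
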
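# SYNTHETIC demonstration coefficient tables for the 10-year ASCVD risk
# engine.  These are NOT published China-PAR coefficients; they are made-up
# values with the same term structure (age, smoking, waist circumference,
# treated/untreated SBP, family history of ASCVD, total cholesterol, HDL-C,
# diabetes, region), intended for tests and worked examples only.  Supply the
# published sex-specific tables in this schema for real scoring.
version: "synthetic-demo-1"
tables:
  female:
    s0: 0.979
    terms:
      - {name: age, transform: identity, field: age, coefficient: 0.075, mean: 55.9}
      - {name: current_smoker, transform: indicator, field: smoking, level: current,
         coefficient: 0.35, mean: 0.05}
      - {name: waist_circumference, transform: identity, field: waist_circumference,
         coefficient: 0.012, mean: 84.2}
      - {name: sbp, transform: identity, field: sbp, coefficient: 0.016, mean: 125.6}
      - {name: bp_treated, transform: indicator, field: bp_treated, level: 1,
         coefficient: 0.30, mean: 0.14}
      - {name: sbp_x_treated, transform: product, factors: [sbp, bp_treated],
         coefficient: -0.004, mean: 17.6}
      - {name: family_history, transform: indicator, field: family_history_ascvd,
         level: 1, coefficient: 0.20, mean: 0.15}
      - {name: log_tc, transform: log, field: total_cholesterol,
         coefficient: 0.55, mean: 5.20}
      - {name: log_hdl, transform: log, field: hdl_cholesterol,
         coefficient: -0.65, mean: 3.91}
      - {name: diabetes, transform: indicator, field: diabetes, level: 1,
         coefficient: 0.50, mean: 0.09}
      - {name: northern_region, transform: indicator, field: region, level: north,
         coefficient: 0.18, mean: 1.0}
  male:
    s0: 0.948
    terms:
      - {name: age, transform: identity, field: age, coefficient: 0.068, mean: 55.9}
      - {name: current_smoker, transform: indicator, field: smoking, level: current,
         coefficient: 0.42, mean: 0.45}
      - {name: waist_circumference, transform: identity, field: waist_circumference,
         coefficient: 0.014, mean: 84.2}
      - {name: sbp, transform: identity, field: sbp, coefficient: 0.015, mean: 125.6}
      - {name: bp_treated, transform: indicator, field: bp_treated, level: 1,
         coefficient: 0.28, mean: 0.14}
      - {name: sbp_x_treated, transform: product, factors: [sbp, bp_treated],
         coefficient: -0.003, mean: 17.6}
      - {name: family_history, transform: indicator, field: family_history_ascvd,
         level: 1, coefficient: 0.22, mean: 0.15}
      - {name: log_tc, transform: log, field: total_cholesterol,
         coefficient: 0.50, mean: 5.20}
      - {name: log_hdl, transform: log, field: hdl_cholesterol,
         coefficient: -0.60, mean: 3.91}
      - {name: diabetes, transform: indicator, field: diabetes, level: 1,
         coefficient: 0.55, mean: 0.09}
      - {name: northern_region, transform: indicator, field: region, level: north,
         coefficient: 0.15, mean: 1.0}
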
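{
  "schema_version": "1.0",
  "annual_discount_rate": 0.045,
  "cycle_length_years": 0.25,
  "horizon_cycles": 40,
  "wtp_usd_per_qaly": 23050,
  "krw_per_usd": 1301.5,
  "nonreimbursement_share": 0.2137,
  "psa_iterations": 10000,
  "start_ages": {"60s": 60, "70s": 70, "80s": 80}
}
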
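schema_version: 1
seed: 11
output_dir: results/demo
paths:
  fixes: null        # produced by the simulate stage
  metadata: null
  deaths: null
  regions: null      # packaged region set
thresholds:
  stopover_km: 50.0
  min_duration_days: 1.0
  cycle_gap_h: 10.0
  uncertainty_max_days: 5.0
  wa_sahara_uncertainty_days: 2.0
  breeding_disc_km: 50.0
mcmc:
  chains: 4
  burn_in: 2000
  draws: 4000
simulate:
  n_birds: 60
  n_years: 3
  duty_on_hours: 10.0
  duty_off_hours: 48.0
  p_missed_cycle: 0.15
  fix_noise_km: 1.5
  flight_speed_kmh: 50.0
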
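designs:
- electrode_insertion_day: -3.0
  electrode_locations:
  - pod
  experiment_id: late_season_r5
  growth_stage: R5
  insects_per_pot: 0
  irrigation_times:
  - 1.5
  - 3.5
  - 5.5
  lights_on_clock_hour: 8.0
  n_pots: 5
  photoperiod_day_hours: 14.0
  photoperiod_night_hours: 10.0
  recording_end_day: 7.0
  recording_start_day: -3.0
  removal_day: null
  sample_interval: 1.0
  treatment: non_infested
- electrode_insertion_day: -3.0
  electrode_locations:
  - pod
  experiment_id: late_season_r5
  growth_stage: R5
  insects_per_pot: 20
  irrigation_times:
  - 1.5
  - 3.5
  - 5.5
  lights_on_clock_hour: 8.0
  n_pots: 5
  photoperiod_day_hours: 14.0
  photoperiod_night_hours: 10.0
  recording_end_day: 7.0
  recording_start_day: -3.0
  removal_day: null
  sample_interval: 1.0
  treatment: infested_untreated
- electrode_insertion_day: -3.0
  electrode_locations:
  - pod
  experiment_id: late_season_r5
  growth_stage: R5
  insects_per_pot: 20
  irrigation_times:
  - 1.5
  - 3.5
  - 5.5
  lights_on_clock_hour: 8.0
  n_pots: 5
  photoperiod_day_hours: 14.0
  photoperiod_night_hours: 10.0
  recording_end_day: 7.0
  recording_start_day: -3.0
  removal_day: null
  sample_interval: 1.0
  treatment: infested_treated
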
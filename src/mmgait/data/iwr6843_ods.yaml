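start_frequency: 60750000000.0
center_frequency: 63008000000.0
sweep_bandwidth: 1780393000.0
n_tx: 3
n_rx: 4
n_samples_per_chirp: 96
n_chirps_per_frame: 288
sampling_rate: 2950000.0
idle_time: 3.0e-05
adc_start_time: 2.5e-05
frame_period: 0.055
range_threshold_db: 15.0
doppler_threshold_db: 15.0
configured_max_doppler: 4.45
configured_doppler_resolution: 0.093
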
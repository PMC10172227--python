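# Illustrative: diffusion-tensor MRI fiber lengths on young subjects; no
# sarcomere measurement possible, so raw lengths stand in for optimal.
schema_version: 1
name: mri_fiber_no_sarcomere
sarcomere_measured: false
fiber_scaled_to_optimal: false
uniform_optimal_sarcomere: false
pennation_scaled: false
pennation_raw_used_in_projected_pcsa: false
fiber_length_source_cohort: young_in_vivo
volume_source_cohort: young_in_vivo
specific_tension_source: same_cohort
tendon_mode: computed_at_measurement_position
raw_pennation_deg: 12.0
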
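# Illustrative: in-vivo MRI volumes from young subjects divided by cadaveric
# optimal fiber lengths; pennation rescaled to optimal; inherited specific
# tension.
schema_version: 1
name: mri_volume_cadaver_fiber
sarcomere_measured: true
fiber_scaled_to_optimal: true
uniform_optimal_sarcomere: true
pennation_scaled: true
pennation_raw_used_in_projected_pcsa: false
fiber_length_source_cohort: elderly_cadaver
volume_source_cohort: young_in_vivo
specific_tension_source: inherited
tendon_mode: computed_at_measurement_position
raw_pennation_deg: 28.3
raw_sarcomere_um: 2.12
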
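# Illustrative: single-specimen cadaveric dataset with directly measured
# tendon lengths used as slack lengths and a literature specific tension.
schema_version: 1
name: single_cadaver_measured_tendon
sarcomere_measured: true
fiber_scaled_to_optimal: true
uniform_optimal_sarcomere: true
pennation_scaled: false
pennation_raw_used_in_projected_pcsa: false
fiber_length_source_cohort: elderly_cadaver
volume_source_cohort: elderly_cadaver
specific_tension_source: inherited
tendon_mode: measured_length
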
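# Illustrative: 21-specimen cadaveric dataset; PCSA recomputed from volume
# and rescaled fiber length within the same cohort; fiber optimality placed
# at the fixation position.
schema_version: 1
name: multi_cadaver_recomputed_pcsa
sarcomere_measured: true
fiber_scaled_to_optimal: true
uniform_optimal_sarcomere: true
pennation_scaled: false
pennation_raw_used_in_projected_pcsa: false
fiber_length_source_cohort: elderly_cadaver
volume_source_cohort: elderly_cadaver
specific_tension_source: inherited
tendon_mode: computed_at_measurement_position
raw_pennation_deg: 28.0
raw_sarcomere_um: 2.12
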
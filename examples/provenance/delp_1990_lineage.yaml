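# Illustrative: elderly-cadaver datasets with sarcomere-based rescaling for
# part of the muscles, manually tuned tendon slack lengths, one specific
# tension per data source.
schema_version: 1
name: delp_1990_lineage
sarcomere_measured: true
fiber_scaled_to_optimal: true
uniform_optimal_sarcomere: true
pennation_scaled: false
pennation_raw_used_in_projected_pcsa: true
fiber_length_source_cohort: elderly_cadaver
volume_source_cohort: elderly_cadaver
specific_tension_source: uniform
tendon_mode: computed_at_calibrated_position
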
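Illustrative provenance metadata pack
=====================================

One YAML file per well-known lower-limb muscle architecture dataset or
model lineage, encoding how its musculotendon parameters were derived so
the `mts audit` rules can be demonstrated. These files are **illustrative
summaries, not authoritative records** — consult the original publications
before drawing conclusions about any specific model. Schema v1 (see
`mts.audit.ProvenanceMetadata`).
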
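# Example complex-membership configuration for chromatin remodeler
# complexes that handle the histone variant H2A.Z. Subunit identifiers are
# transcribed verbatim from the source figure legends (including their
# capitalisation); edit freely to match the identifiers in your own
# intensity tables.
p400-TIP60:
  - EP400
  - KAT5
  - RUVBl1
  - RUVBl2
  - VPS72
SRCAP:
  - SRCAP
  - ZNHIT11
  - RUVBl1
  - RUVBl2
  - VPS72
INO80:
  - INO80
  - RUVBl1
  - RUVBl2
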
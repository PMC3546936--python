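{
  "raw_reads": 14919026,
  "unique_sequences": 161288,
  "clean_reads": 9320178,
  "ncrna_reads_removed": 2679012,
  "mapped_reads": 4542396,
  "mapped_unique_sequences": 25538,
  "conserved_mirnas": 237,
  "conserved_families": 105,
  "duplex_pairs": 120,
  "pct_reads_21_23nt": 54.8
}
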
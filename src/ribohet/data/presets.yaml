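# Species presets: concatenation order of the selected rRNA variants and the
# circular background-shift distance (nt, ~1% of total rRNA length).
# Sequence FASTA and structure files are user-supplied (see README);
# 4v6x_A7 denotes the 5S rRNA chain A7 of PDB 4V6X.
human:
  rrna_order: [NR_003287.4, NR_003286.4, NR_003285.3, 4v6x_A7]
  rrna_names: [28S, 18S, 5.8S, 5S]
  shift: 71
  structure: 4V6X
mouse:
  rrna_order: [NR_003279.1, NR_003278.3, NR_003280.2, NR_030686.1]
  rrna_names: [28S, 18S, 5.8S, 5S]
  shift: 67
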
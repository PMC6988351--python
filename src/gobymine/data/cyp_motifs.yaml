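# Surrogate PROSITE-style patterns with the canonical consensus shapes
# of the four conserved cytochrome P450 motifs. Override any entry with
# a curated pattern set via --config / load_cyp_motifs(path).
motifs:
  I-helix: "[AG]-G-x-[DE]-T-[TS]"
  K-helix: "E-x-x-R"
  meander: "P-x-R-[FWH]"
  heme-loop: "F-x-x-G-x-x-x-C-x-G"
rules:
  full_length_aa: 500
  tolerance_aa: 50
  core_region_aa: 120
  require_start: true
  require_stop: true
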
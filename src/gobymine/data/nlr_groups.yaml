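# The six NLR-C groups: conserved Walker A motif patterns plus whether
# members may carry an N-terminal PYD and/or C-terminal B30.2 domain.
# Patterns use PROSITE syntax, extended with (AB/CD) multi-residue
# alternatives; a leading x is one arbitrary residue.
groups:
  - {id: 1, walker_a: "G-I-A-G-V-G-K-T-L-[IM]-P-V-V-K-N-T-[TR]-R-A", pyd: true,  b30_2: true}
  - {id: 2, walker_a: "G-V-A-G-I-G-K-S-L-S-A-V-I-K-T-S-K-R-A",       pyd: true,  b30_2: true}
  - {id: 3, walker_a: "G-I-A-G-I-G-K-T-L-(IP/TA)-A-V-[RS]-N-C-(RK/TR/RR)-A", pyd: false, b30_2: true}
  - {id: 4, walker_a: "G-V-A-G-I-G-K-T-L-P-V-[IV]-x-x-x-x-[AV]-x",   pyd: false, b30_2: false}
  - {id: 5, walker_a: "x-G-V-A-G-[VI]-G-K-T-[LM]-P-V-[VI]-K-A-S-x-K-[AV]", pyd: true, b30_2: true}
  - {id: 6, walker_a: "x-G-V-A-G-V-G-K-T-L-[IV]-P-[AV]-V-R-N-C-R-K-A", pyd: false, b30_2: false}
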
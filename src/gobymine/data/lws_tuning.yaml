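# Additive five-sites tuning model for LWS opsins.
# Sites are in bovine-rhodopsin numbering; shifts in nm per substitution
# away from the ancestral residue (literature defaults of the
# five-sites rule).
sites: [164, 181, 261, 269, 292]
baseline_residues: SHYTA
baseline_lambda_max: 560.0
shifts:
  - {site: 164, from: S, to: A, delta_nm: -7.0}
  - {site: 181, from: H, to: Y, delta_nm: -28.0}
  - {site: 261, from: Y, to: F, delta_nm: -10.0}
  - {site: 269, from: T, to: A, delta_nm: -15.0}
  - {site: 292, from: A, to: S, delta_nm: -27.0}
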
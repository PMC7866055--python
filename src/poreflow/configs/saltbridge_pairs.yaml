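# Named salt-bridge pair sets (acidic resid, basic resid), author numbering.
ucp2_matrix:
  - [35, 141]    # Asp35-Lys141
  - [236, 38]    # Asp236-Lys38
  - [138, 239]   # Asp138-Lys239
ucp2_cytosolic:
  - [198, 104]   # Asp198-Lys104
  - [101, 295]   # Asp101-Lys295
  - [292, 201]   # Glu292-Lys201
ant_matrix:
  - [29, 137]    # Glu29-Arg137
  - [231, 32]    # Asp231-Lys32
  - [134, 234]   # Asp134-Arg234
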
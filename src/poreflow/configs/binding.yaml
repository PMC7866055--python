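# Ligand-binding analysis defaults for the UCP2 nucleotide/fatty-acid work.
ucp2_atp_arginines: [88, 185, 279]
contact_cutoff_nm: 0.35
phosphate_bound_cutoff_nm: 0.6
# last half of each replica (e.g. last 10 ns of 20 ns; first half equilibration)
analysis_window: [0.5, 1.0]
fatty_acid_site_resid: 60
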
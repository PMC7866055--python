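# Pore-region ring definitions (author residue numbering, one C-alpha per
# residue per ring) for the carrier structures analysed in the literature.
# The NMR-based model uses six C-alpha atoms per ring; the homology-based
# model's printed lists carry five. Radius in nm.
ucp2_nmr:
  bottom: [34, 85, 137, 181, 239, 274]
  top: [20, 101, 120, 194, 227, 288]
  radius: 2.0
ucp2_h:
  bottom: [34, 82, 137, 181, 274]
  top: [20, 101, 120, 192, 288]
  radius: 2.0
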
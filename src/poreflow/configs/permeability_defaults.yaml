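# Collective-diffusion permeability protocol defaults.
radius_nm: 2.0
n_subtraj: 100
subtraj_len_ps: 50.0
viscosity_scale: 2.87
water_molecule_volume_cm3: 2.99e-23
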
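"""Water density profile, volume-map continuity and crossing counts.

The open pore shows a continuous water column through the membrane slab
and a steady trickle of complete traversals; the closed pore splits the
water into two disjoint reservoirs and shows zero crossings.
"""

import numpy as np

from poreflow import (
    PoreParams,
    SyntheticSpec,
    count_crossings,
    is_channel_continuous,
    make_pore_system,
    occupancy_grid,
    select,
    z_density_profile,
)

for label, barrier in (("open", False), ("closed", True)):
    spec = SyntheticSpec(kind="pore", seed=3, n_frames=4000, dt=0.5,
                         pore=PoreParams(barrier=barrier))
    traj, _ = make_pore_system(spec)
    waters = select(traj.topology, "water")
    axis = select(traj.topology, "name CA")

    prof = z_density_profile(traj, waters, axis, lateral_radius=1.0, bin_width=0.25)
    mid = np.abs(prof.z_bin_centers) < spec.pore.half_length
    print(f"{label} pore:")
    print(f"  mean density inside the slab  = {prof.density[mid].mean():.2f} per nm^3")

    # synthetic water is ~20x more dilute than liquid water, so the voxel
    # size / isovalue pair is scaled accordingly (presence fractions are
    # proportional to density x voxel volume)
    grid = occupancy_grid(traj, waters,
                          (np.array([-1.0, -1.0, -1.5]), np.array([1.0, 1.0, 1.5])),
                          spacing=0.5)
    cont = is_channel_continuous(grid, isovalue=0.1)
    print(f"  volume map continuous along z = {cont.continuous} "
          f"({cont.n_components} component(s), extent {cont.extent_nm:.2f} nm)")

    rep = count_crossings(traj, waters, -spec.pore.half_length,
                          spec.pore.half_length, 2.0, axis)
    print(f"  complete crossings            = {rep.n_up} up, {rep.n_down} down")

print("\nA thresholded volume map that connects both faces of the slab is the"
      "\nwater-channel signature; a sealed pore shows two disjoint volumes"
      "\nand no complete traversals.")
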
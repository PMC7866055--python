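"""Water osmotic permeability of an open vs a closed channel.

Generates two synthetic systems — a water-filled cylindrical pore and its
closed (dewetted) counterpart — and runs the collective-diffusion route:
n(t) accumulation, the <n^2> = 2*Dn*t fit over 100 x 50 ps blocks, and
Pf = vw * Dn with the rigid-water viscosity correction.
"""

from poreflow import (
    PoreParams,
    SyntheticSpec,
    define_pore_region,
    make_pore_system,
    permeability_from_trajectory,
    select,
)

for label, barrier in (("open pore", False), ("closed (dewetted) pore", True)):
    spec = SyntheticSpec(kind="pore", seed=1, n_frames=10_000, dt=0.5,
                         pore=PoreParams(barrier=barrier))
    traj, truth = make_pore_system(spec)
    n_ring = spec.pore.n_ring_atoms
    region = define_pore_region(traj.topology, list(range(1, n_ring + 1)),
                                list(range(n_ring + 1, 2 * n_ring + 1)))
    _series, fit, result = permeability_from_trajectory(
        traj, region, select(traj.topology, "water"))
    print(f"{label}:")
    print(f"  mean channel occupancy  = {truth.mean_channel_occupancy:.2f} waters")
    print(f"  fitted Dn               = {fit.Dn:.3e} +- {fit.se:.1e} 1/ps "
          f"(analytic {truth.expected_Dn:.3e})")
    print(f"  Pf                      = {result.Pf:.3e} cm^3/s")

print("\nDn is the diffusion coefficient of the collective water coordinate;"
      "\nfor independent waters it equals N_in * D / L^2. The closed pore is"
      "\ndry, so n(t) stays at zero and Pf vanishes — the open/closed contrast"
      "\nis the signature separating a leaky channel from a sealed carrier.")
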
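"""Synthetic trajectory generators with analytic ground truth.

Three system kinds emulate the statistical structure that each analysis
stage assumes, so the whole pipeline is testable without an MD engine:

``pore``
    Non-interacting Brownian "waters" (single pseudo-atoms, per-axis step
    variance ``2*D*dt``) around a cylindrical channel spanning a membrane
    slab, delimited by two static rings of pseudo-C-alpha atoms.  The open
    variant admits waters into the channel (reflecting radial wall,
    periodic z outside the slab); for independent particles the collective
    diffusion coefficient is exactly ``N_in * D / L**2`` with ``N_in`` the
    time-average channel occupancy and ``L`` the channel length.  The
    closed variant (``barrier=True``) models a pore whose constriction has
    dewetted the channel: the whole slab, channel included, is reflecting,
    so the water distribution splits into two disjoint reservoirs and both
    the crossing count and the collective diffusion vanish.

``saltbridge``
    Two three-atom pseudo-residues whose centre-of-mass separation follows
    a two-state telegraph process (rates ``k_on``, ``k_off``) between a
    bound and an unbound mean distance plus Gaussian noise; the stationary
    bound fraction is ``k_on / (k_on + k_off)`` in closed form.

``binding``
    A static binding-site atom plus a jittered bead chain whose head is
    tethered at a controlled distance; ground-truth contact counts come
    from an exhaustive pairwise recount of the generated coordinates.

All randomness flows from a single ``numpy`` generator seeded by
``SyntheticSpec.seed``; identical specs produce identical trajectories.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .md_io import Frame, Topology, Trajectory, assign_masses, write_trajectory

__all__ = [
    "PoreParams",
    "SaltBridgeParams",
    "BindingParams",
    "SyntheticSpec",
    "GroundTruth",
    "make_pore_system",
    "make_saltbridge_system",
    "make_binding_system",
    "generate",
    "write_system",
]


@dataclass(frozen=True)
class PoreParams:
    """Geometry of the synthetic channel (all lengths nm)."""

    ring_radius: float = 1.0       # radius at which the pseudo-CA ring atoms sit
    half_length: float = 1.0       # slab half-thickness; channel length L = 2*half_length
    n_ring_atoms: int = 6          # atoms per ring
    channel_radius: float = 1.0    # reflecting radial wall of the channel
    barrier: bool = False          # True -> closed (dewetted) channel


@dataclass(frozen=True)
class WaterParams:
    count: int = 112               # chosen so the default geometry holds ~10 waters in-channel
    D: float = 2.3e-3              # nm^2/ps, TIP3P-like self-diffusion


@dataclass(frozen=True)
class SaltBridgeParams:
    bound_mean: float = 0.45       # nm, COM separation in the bound state
    unbound_mean: float = 0.95     # nm, COM separation in the broken state
    noise_sd: float = 0.05         # nm
    k_on: float = 0.05             # 1/ps, unbound -> bound
    k_off: float = 0.05            # 1/ps, bound -> unbound


@dataclass(frozen=True)
class BindingParams:
    n_beads: int = 20
    tether_distance: float = 0.30  # nm, head bead to site atom
    bead_spacing: float = 0.13     # nm
    jitter_sd: float = 0.02        # nm, per-frame Gaussian jitter of the chain
    cutoff: float = 0.35           # nm, contact cutoff used for the ground truth


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterisation of a generated system.

    ``kind`` selects which parameter block applies; ``box`` is the
    orthorhombic box (nm) and ``dt`` the frame spacing (ps).
    """

    kind: str = "pore"             # pore | saltbridge | binding
    seed: int = 0
    n_frames: int = 10_000
    dt: float = 0.5
    box: tuple[float, float, float] = (4.0, 4.0, 6.0)
    pore: PoreParams = field(default_factory=PoreParams)
    waters: WaterParams = field(default_factory=WaterParams)
    saltbridge: SaltBridgeParams = field(default_factory=SaltBridgeParams)
    binding: BindingParams = field(default_factory=BindingParams)

    def __post_init__(self) -> None:
        if self.kind not in ("pore", "saltbridge", "binding"):
            raise ValueError(f"unknown synthetic system kind {self.kind!r}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be at least 1")
        if self.waters.D <= 0:
            raise ValueError("water diffusion coefficient must be positive")
        sb = self.saltbridge
        if not 0 < sb.bound_mean < sb.unbound_mean:
            raise ValueError("need 0 < bound_mean < unbound_mean")


@dataclass
class GroundTruth:
    """Analytic expectations for the matching system kind (others None)."""

    expected_Dn: float | None = None              # 1/ps (pore)
    expected_crossing_rate: float | None = None   # events/ns per direction (pore)
    expected_occupancy: float | None = None       # bound fraction (saltbridge)
    expected_contacts: np.ndarray | None = None   # per-frame counts (binding)
    mean_channel_occupancy: float | None = None   # time-average N_in (pore)


# ---------------------------------------------------------------------------
# pore system


def _pore_topology(spec: SyntheticSpec) -> Topology:
    n_ring = spec.pore.n_ring_atoms
    names = ["CA"] * (2 * n_ring) + ["OW"] * spec.waters.count
    resnames = ["RNG"] * (2 * n_ring) + ["SOL"] * spec.waters.count
    resids = list(range(1, 2 * n_ring + 1)) + list(
        range(2 * n_ring + 1, 2 * n_ring + 1 + spec.waters.count)
    )
    resindices = np.arange(len(names))
    return Topology(
        names=np.array(names, dtype=object),
        resids=np.array(resids, dtype=int),
        resnames=np.array(resnames, dtype=object),
        resindices=resindices,
        masses=assign_masses(names, resnames),
    )


def _ring_positions(spec: SyntheticSpec) -> np.ndarray:
    p = spec.pore
    angles = 2 * np.pi * np.arange(p.n_ring_atoms) / p.n_ring_atoms
    ring = np.column_stack([p.ring_radius * np.cos(angles),
                            p.ring_radius * np.sin(angles),
                            np.zeros_like(angles)])
    bottom = ring + np.array([0.0, 0.0, -p.half_length])
    top = ring + np.array([0.0, 0.0, p.half_length])
    return np.vstack([bottom, top])


def _init_waters(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Uniform placement in the water-accessible volume (rejection sampling)."""
    p, box = spec.pore, np.asarray(spec.box)
    out = np.empty((spec.waters.count, 3))
    n = 0
    while n < spec.waters.count:
        cand = rng.uniform(-box / 2, box / 2, size=(spec.waters.count, 3))
        rad = np.hypot(cand[:, 0], cand[:, 1])
        in_slab = np.abs(cand[:, 2]) < p.half_length
        if p.barrier:
            ok = ~in_slab
        else:
            ok = ~in_slab | (rad < p.channel_radius)
        take = cand[ok][: spec.waters.count - n]
        out[n : n + len(take)] = take
        n += len(take)
    return out


def _advance_waters(pos: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """One Brownian step with wall handling; returns new positions.

    Reflection is applied per event (one pass); steps are much smaller than
    any geometric feature, so corner-cutting is bounded by one step's
    displacement.
    """
    p, box = spec.pore, np.asarray(spec.box)
    sigma = np.sqrt(2 * spec.waters.D * spec.dt)
    old = pos
    new = pos + rng.normal(0.0, sigma, pos.shape)
    new = new - box * np.round(new / box)  # periodic wrap, box centred on origin
    h, a = p.half_length, p.channel_radius
    old_in_slab = np.abs(old[:, 2]) < h
    new_in_slab = np.abs(new[:, 2]) < h
    rad = np.hypot(new[:, 0], new[:, 1])
    if p.barrier:
        # closed pore: the whole slab (channel included) is impenetrable
        hit = new_in_slab
        face = np.where(old[hit, 2] >= 0, h, -h)
        new[hit, 2] = 2 * face - new[hit, 2]
    else:
        # bulk water bouncing off a slab face (outside the channel mouth)
        hit = ~old_in_slab & new_in_slab & (rad >= a)
        face = np.sign(old[hit, 2]) * h
        new[hit, 2] = 2 * face - new[hit, 2]
        # channel water reflecting off the radial wall
        new_in_slab = np.abs(new[:, 2]) < h
        rad = np.hypot(new[:, 0], new[:, 1])
        hit = old_in_slab & new_in_slab & (rad >= a)
        r_ref = np.maximum(2 * a - rad[hit], 1e-9)
        scale = r_ref / rad[hit]
        new[hit, 0] *= scale
        new[hit, 1] *= scale
    return new


def make_pore_system(spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """Generate the cylindrical-pore water system and its ground truth."""
    if spec.kind != "pore":
        raise ValueError("spec.kind must be 'pore'")
    if spec.waters.count == 0:
        raise ValueError("waters.count must be positive")
    box = np.asarray(spec.box, dtype=float)
    p = spec.pore
    if p.channel_radius >= min(box[0], box[1]) / 2:
        raise ValueError("channel_radius must be smaller than half the lateral box")
    if 2 * p.half_length >= box[2]:
        raise ValueError("slab thicker than the box; no reservoirs left")
    rng = np.random.default_rng(spec.seed)
    rings = _ring_positions(spec)
    topo = _pore_topology(spec)
    waters = _init_waters(spec, rng)
    frames = []
    occ_sum = 0
    for i in range(spec.n_frames):
        if i > 0:
            waters = _advance_waters(waters, spec, rng)
        occ_sum += int(np.count_nonzero(
            (np.abs(waters[:, 2]) < p.half_length)
            & (np.hypot(waters[:, 0], waters[:, 1]) < p.channel_radius)
        ))
        frames.append(Frame(time=i * spec.dt,
                            positions=np.vstack([rings, waters]),
                            box=box.copy()))
    n_in = occ_sum / spec.n_frames
    L = 2 * p.half_length
    if p.barrier:
        truth = GroundTruth(expected_Dn=0.0, expected_crossing_rate=0.0,
                            mean_channel_occupancy=n_in)
    else:
        dn = n_in * spec.waters.D / L**2
        truth = GroundTruth(expected_Dn=dn, expected_crossing_rate=1000.0 * dn,
                            mean_channel_occupancy=n_in)
    return Trajectory(topology=topo, frames=frames, dt=spec.dt), truth


# ---------------------------------------------------------------------------
# salt-bridge system

# rigid 3-atom templates with unequal masses (C, C, O / C, C, N)
_ACID_TEMPLATE = (("CB", [0.00, 0.00, 0.00]), ("CG", [0.15, 0.00, 0.00]),
                  ("OD1", [0.21, 0.11, 0.00]))
_BASE_TEMPLATE = (("CD", [0.00, 0.00, 0.00]), ("CE", [-0.15, 0.00, 0.00]),
                  ("NZ", [-0.21, -0.11, 0.00]))


def make_saltbridge_system(spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """Two pseudo-residues with a telegraph-process COM separation."""
    if spec.kind != "saltbridge":
        raise ValueError("spec.kind must be 'saltbridge'")
    sb = spec.saltbridge
    if sb.noise_sd >= (sb.unbound_mean - sb.bound_mean) / 2:
        raise ValueError("noise_sd too large: bound/unbound states must be separable")
    box = np.asarray(spec.box, dtype=float)
    rng = np.random.default_rng(spec.seed)

    names = [n for n, _ in _ACID_TEMPLATE] + [n for n, _ in _BASE_TEMPLATE]
    resnames = ["ASP"] * 3 + ["LYS"] * 3
    topo = Topology(
        names=np.array(names, dtype=object),
        resids=np.array([1, 1, 1, 2, 2, 2], dtype=int),
        resnames=np.array(resnames, dtype=object),
        resindices=np.array([0, 0, 0, 1, 1, 1], dtype=int),
        masses=assign_masses(names, resnames),
    )
    acid = np.array([x for _, x in _ACID_TEMPLATE])
    base = np.array([x for _, x in _BASE_TEMPLATE])
    m_acid = topo.masses[:3]
    m_base = topo.masses[3:]
    acid_com = (acid * m_acid[:, None]).sum(axis=0) / m_acid.sum()
    base_com = (base * m_base[:, None]).sum(axis=0) / m_base.sum()

    # exact two-state CTMC transition probabilities over one frame interval:
    # preserves the stationary bound fraction k_on/(k_on+k_off) for any dt
    k_tot = sb.k_on + sb.k_off
    p_bound = sb.k_on / k_tot if k_tot > 0 else 1.0
    relax = -np.expm1(-k_tot * spec.dt)  # 1 - exp(-(k_on+k_off)*dt)
    p_on = p_bound * relax               # unbound -> bound
    p_off = (1.0 - p_bound) * relax      # bound -> unbound
    bound = bool(rng.random() < p_bound)

    frames = []
    bound_frames = 0
    for i in range(spec.n_frames):
        if i > 0:
            u = rng.random()
            if bound and u < p_off:
                bound = False
            elif not bound and u < p_on:
                bound = True
        bound_frames += bound
        d = (sb.bound_mean if bound else sb.unbound_mean) + rng.normal(0.0, sb.noise_sd)
        d = max(d, 0.05)
        pos = np.vstack([
            acid - acid_com,
            base - base_com + np.array([d, 0.0, 0.0]),
        ])
        frames.append(Frame(time=i * spec.dt, positions=pos, box=box.copy()))
    truth = GroundTruth(expected_occupancy=p_bound)
    return Trajectory(topology=topo, frames=frames, dt=spec.dt), truth


# ---------------------------------------------------------------------------
# binding system


def make_binding_system(spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """Static binding-site atom plus a tethered, jittered bead chain."""
    if spec.kind != "binding":
        raise ValueError("spec.kind must be 'binding'")
    b = spec.binding
    if b.n_beads < 1:
        raise ValueError("n_beads must be at least 1")
    box = np.asarray(spec.box, dtype=float)
    rng = np.random.default_rng(spec.seed)

    names = ["CZ"] + [f"C{i+1}" for i in range(b.n_beads)]
    resnames = ["ARG"] + ["AA"] * b.n_beads
    topo = Topology(
        names=np.array(names, dtype=object),
        resids=np.array([1] + [2] * b.n_beads, dtype=int),
        resnames=np.array(resnames, dtype=object),
        resindices=np.array([0] + [1] * b.n_beads, dtype=int),
        masses=assign_masses(names, resnames),
    )
    site = np.zeros((1, 3))
    chain0 = np.column_stack([
        b.tether_distance + b.bead_spacing * np.arange(b.n_beads),
        np.zeros(b.n_beads),
        np.zeros(b.n_beads),
    ])
    frames = []
    counts = np.empty(spec.n_frames, dtype=int)
    for i in range(spec.n_frames):
        chain = chain0 + rng.normal(0.0, b.jitter_sd, chain0.shape)
        pos = np.vstack([site, chain])
        # exhaustive ground-truth recount (minimum image irrelevant: box >> chain)
        delta = chain[:, None, :] - site[None, :, :]
        delta -= box * np.round(delta / box)
        counts[i] = int(np.count_nonzero(np.linalg.norm(delta, axis=-1) < b.cutoff))
        frames.append(Frame(time=i * spec.dt, positions=pos, box=box.copy()))
    truth = GroundTruth(expected_contacts=counts)
    return Trajectory(topology=topo, frames=frames, dt=spec.dt), truth


_MAKERS = {
    "pore": make_pore_system,
    "saltbridge": make_saltbridge_system,
    "binding": make_binding_system,
}


def generate(spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """Dispatch to the generator matching ``spec.kind``."""
    return _MAKERS[spec.kind](spec)


def write_system(prefix: str | Path, traj: Trajectory, spec: SyntheticSpec,
                 truth: GroundTruth) -> tuple[Path, Path]:
    """Write a generated system as multi-frame GRO plus a JSON sidecar.

    The sidecar records the full spec and the ground truth, so a run can be
    replayed or validated without regenerating.
    """
    prefix = Path(prefix)
    gro = prefix.with_suffix(".gro")
    sidecar = prefix.with_suffix(".json")
    write_trajectory(gro, traj, format="GRO", title=f"poreflow synthetic {spec.kind}")
    payload = {
        "spec": dataclasses.asdict(spec),
        "ground_truth": {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in dataclasses.asdict(truth).items()
        },
    }
    sidecar.write_text(json.dumps(payload, indent=2))
    return gro, sidecar
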
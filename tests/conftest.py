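"""Shared fixtures: small synthetic systems reused across test modules."""

import numpy as np
import pytest

from poreflow import (
    PoreParams,
    SyntheticSpec,
    Topology,
    Frame,
    Trajectory,
    make_pore_system,
)
from poreflow.md_io import assign_masses


@pytest.fixture(scope="session")
def open_pore_system():
    """Open-pore Brownian system, long enough for a 20-block MSD fit."""
    spec = SyntheticSpec(kind="pore", seed=11, n_frames=4000)
    traj, truth = make_pore_system(spec)
    return spec, traj, truth


@pytest.fixture(scope="session")
def closed_pore_system():
    spec = SyntheticSpec(kind="pore", seed=11, n_frames=2000,
                         pore=PoreParams(barrier=True))
    traj, truth = make_pore_system(spec)
    return spec, traj, truth


def make_trajectory(positions_per_frame, box=(10.0, 10.0, 10.0), dt=1.0,
                    names=None, resids=None, resnames=None, masses=None):
    """Hand-build a Trajectory from raw coordinate arrays (test helper)."""
    frames = [np.asarray(p, dtype=float) for p in positions_per_frame]
    n_atoms = frames[0].shape[0]
    names = list(names) if names is not None else [f"A{i}" for i in range(n_atoms)]
    resids = list(resids) if resids is not None else list(range(1, n_atoms + 1))
    resnames = list(resnames) if resnames is not None else ["RES"] * n_atoms
    if masses is None:
        masses = np.ones(n_atoms)
    order = {}
    resindices = np.array([order.setdefault(r, len(order)) for r in resids])
    topo = Topology(
        names=np.array(names, dtype=object),
        resids=np.array(resids, dtype=int),
        resnames=np.array(resnames, dtype=object),
        resindices=resindices,
        masses=np.asarray(masses, dtype=float),
    )
    box = np.asarray(box, dtype=float)
    return Trajectory(
        topology=topo,
        frames=[Frame(time=i * dt, positions=p, box=box.copy())
                for i, p in enumerate(frames)],
        dt=dt,
    )


@pytest.fixture
def traj_builder():
    return make_trajectory
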
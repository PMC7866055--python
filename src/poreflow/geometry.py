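"""Shared periodic-boundary geometry helpers (orthorhombic boxes only)."""

from __future__ import annotations

import numpy as np

from .md_io import Topology, Trajectory

__all__ = ["minimum_image", "residue_com_series"]


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Map displacement vectors to their nearest periodic image."""
    return delta - box * np.round(delta / box)


def residue_com_series(traj: Trajectory, resid: int) -> np.ndarray:
    """Per-frame mass-weighted centre of mass (nm) of one residue.

    Residue atoms are made whole across the periodic boundary (minimum
    image relative to the residue's first atom) before averaging, so a
    residue straddling the box edge gets a physically meaningful COM.
    """
    topo: Topology = traj.topology
    idx = topo.residue_atoms(resid)
    masses = topo.masses[idx]
    wn = masses / masses.sum()
    out = np.empty((traj.n_frames, 3))
    for i, frame in enumerate(traj.frames):
        pos = frame.positions[idx]
        anchor = pos[0]
        whole = anchor + minimum_image(pos - anchor, frame.box)
        out[i] = (whole * wn[:, None]).sum(axis=0)
    return out
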
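"""Ligand-binding geometry and contact analyses.

Covers contact counting at a distance cutoff (ATP / fatty-acid anion
versus protein), phosphate-to-arginine distance statistics over replica
ensembles with an equilibration window, and monitoring of the salt bridge
between a binding-site residue (e.g. the fatty-acid site arginine) and a
ligand head group.

Conventions: a "contact" is any interatomic pair within the cutoff,
counted per pair (``count_unique_atoms=True`` switches to counting
distinct ligand atoms in contact).  Replica statistics report the sample
standard deviation (``ddof=1``) across replicas.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import minimum_image, residue_com_series
from .md_io import Selection, Trajectory
from .saltbridge import DEFAULT_THRESHOLD, SaltBridgePairResult

__all__ = [
    "DEFAULT_CONTACT_CUTOFF",
    "DEFAULT_BOUND_CUTOFF",
    "ContactSeries",
    "ReplicaEnsemble",
    "PhosphateBindingSummary",
    "contact_count_series",
    "apply_analysis_window",
    "phosphate_arginine_summary",
    "binding_site_saltbridge",
]

DEFAULT_CONTACT_CUTOFF = 0.35  # nm
DEFAULT_BOUND_CUTOFF = 0.60    # nm, P-to-arginine-COM "bound" criterion


@dataclass(frozen=True)
class ContactSeries:
    times: np.ndarray      # ps
    counts: np.ndarray     # non-negative integers
    cutoff: float          # nm
    group_a: str
    group_b: str


def _pair_counts(pos_a: np.ndarray, pos_b: np.ndarray, box: np.ndarray,
                 cutoff: float, unique_atoms: bool) -> int:
    delta = minimum_image(pos_a[:, None, :] - pos_b[None, :, :], box)
    close = (delta**2).sum(axis=-1) < cutoff**2
    if unique_atoms:
        return int(np.count_nonzero(close.any(axis=1)))
    return int(np.count_nonzero(close))


def contact_count_series(
    traj: Trajectory,
    group_a: Selection,
    group_b: Selection,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    count_unique_atoms: bool = False,
) -> ContactSeries:
    """Per-frame count of inter-group atom pairs within ``cutoff`` (minimum image).

    Groups must be disjoint.  Sub-group variants (e.g. the ligand carboxyl
    carbon only) are expressed by passing a narrower selection.
    """
    if np.intersect1d(group_a.indices, group_b.indices).size:
        raise ValueError("contact groups must be disjoint")
    counts = np.empty(traj.n_frames, dtype=int)
    for i, frame in enumerate(traj.frames):
        counts[i] = _pair_counts(
            frame.positions[group_a.indices], frame.positions[group_b.indices],
            frame.box, cutoff, count_unique_atoms,
        )
    return ContactSeries(times=traj.times, counts=counts, cutoff=cutoff,
                         group_a=group_a.label, group_b=group_b.label)


@dataclass(frozen=True)
class ReplicaEnsemble:
    """Independent replica trajectories sharing one topology layout.

    ``analysis_window`` is a (start, end) fraction of each replica; the
    default keeps the last half (e.g. the last 10 ns of 20 ns runs, the
    first half being equilibration).
    """

    replicas: list[Trajectory]
    analysis_window: tuple[float, float] = (0.5, 1.0)

    def __post_init__(self) -> None:
        if not self.replicas:
            raise ValueError("ensemble needs at least one replica")
        start, end = self.analysis_window
        if not (0 <= start < end <= 1):
            raise ValueError("analysis_window must satisfy 0 <= start < end <= 1")


def apply_analysis_window(ensemble: ReplicaEnsemble) -> ReplicaEnsemble:
    """Truncate every replica to its analysis window (fractions of frames)."""
    start, end = ensemble.analysis_window
    out = []
    for rep in ensemble.replicas:
        i0 = int(start * rep.n_frames)
        i1 = int(np.ceil(end * rep.n_frames))
        frames = rep.frames[i0:i1]
        if not frames:
            raise ValueError("analysis window leaves no frames")
        out.append(Trajectory(topology=rep.topology, frames=frames, dt=rep.dt))
    return ReplicaEnsemble(replicas=out, analysis_window=(0.0, 1.0))


@dataclass(frozen=True)
class PhosphateBindingSummary:
    """Mean +- SD of P-atom-to-arginine-COM distances over the ensemble.

    ``table`` has one row per (phosphate, arginine) pair with the
    across-replica mean of per-replica window means, the sample SD, and a
    bound flag at ``bound_cutoff``; ``per_replica`` keeps the underlying
    per-replica means.
    """

    table: pd.DataFrame
    per_replica: pd.DataFrame
    bound_cutoff: float


def phosphate_arginine_summary(
    ensemble: ReplicaEnsemble,
    p_atoms: dict[str, Selection],
    arginines: list[int],
    bound_cutoff: float = DEFAULT_BOUND_CUTOFF,
) -> PhosphateBindingSummary:
    """Phosphate-arginine binding geometry over a replica ensemble.

    For each phosphorus atom (e.g. P-alpha/beta/gamma of ATP) and each
    listed arginine, the minimum-image distance from the P atom to the
    arginine's whole-residue COM is averaged over each replica's analysis
    window, then across replicas.  Distances are always reported alongside
    the bound flag so conclusions never rest on the cutoff alone.
    """
    windowed = apply_analysis_window(ensemble)
    rows = []
    for i_rep, rep in enumerate(windowed.replicas):
        boxes = rep.boxes()
        for p_label, p_sel in p_atoms.items():
            if len(p_sel) != 1:
                raise ValueError(
                    f"replica {i_rep}: phosphate selection {p_label!r} must be a single atom"
                )
            p_xyz = rep.coordinates(p_sel.indices)[:, 0, :]
            for arg in arginines:
                try:
                    com = residue_com_series(rep, arg)
                except KeyError:
                    raise KeyError(f"replica {i_rep}: arginine residue {arg} missing")
                d = np.linalg.norm(minimum_image(p_xyz - com, boxes), axis=1)
                rows.append({"replica": i_rep, "p_atom": p_label, "arg_resid": arg,
                             "mean_nm": float(d.mean())})
    per_replica = pd.DataFrame(rows)
    grouped = per_replica.groupby(["p_atom", "arg_resid"])["mean_nm"]
    table = grouped.agg(mean_nm="mean", sd_nm=lambda s: s.std(ddof=1)).reset_index()
    table["sd_nm"] = table["sd_nm"].fillna(0.0)
    table["bound"] = table["mean_nm"] < bound_cutoff
    return PhosphateBindingSummary(table=table, per_replica=per_replica,
                                   bound_cutoff=bound_cutoff)


def binding_site_saltbridge(
    traj: Trajectory,
    site_resid: int,
    ligand_head: Selection,
    threshold: float = DEFAULT_THRESHOLD,
) -> SaltBridgePairResult:
    """Salt-bridge monitor between a binding-site residue and a ligand head group.

    Distance series between the site residue's whole-residue COM and the
    mass-weighted COM of the ligand head selection (e.g. the fatty-acid
    carboxylate), with occupancy at ``threshold`` computed exactly as in
    the salt-bridge module.  Contrasting a wild-type site against a
    mutated one (where no salt bridge forms) is the intended use.
    """
    if len(ligand_head) == 0:
        raise ValueError("ligand head selection is empty")
    site = residue_com_series(traj, site_resid)
    masses = traj.topology.masses[ligand_head.indices]
    wn = masses / masses.sum()
    head = np.empty((traj.n_frames, 3))
    for i, frame in enumerate(traj.frames):
        pos = frame.positions[ligand_head.indices]
        whole = pos[0] + minimum_image(pos - pos[0], frame.box)
        head[i] = (whole * wn[:, None]).sum(axis=0)
    d = np.linalg.norm(minimum_image(head - site, traj.boxes()), axis=1)
    occ = float(np.count_nonzero(d < threshold)) / len(d)
    topo = traj.topology
    site_name = str(topo.resnames[topo.residue_atoms(site_resid)[0]])
    return SaltBridgePairResult(
        pair_label=f"{site_name.capitalize()}{site_resid}-{ligand_head.label}",
        times=traj.times, distances=d, occupancy=occ, threshold=threshold,
    )
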
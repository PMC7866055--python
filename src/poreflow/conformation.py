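"""Conformational stability and flexibility metrics.

Superposition (Kabsch), RMSD time series, RMSF residue profiles, principal
component analysis over pooled trajectories ("common" PCA: one covariance of
the jointly superposed ensembles, then separate projection per trajectory)
and the convex-hull area spanned by the first two principal components.

Superposition and RMSD are mass-weighted by default, following the
convention of the GROMACS family of analysis tools; pass unit weights to
disable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.transform import Rotation

from .md_io import Frame, Selection, Trajectory

__all__ = [
    "SuperpositionResult",
    "RmsdSeries",
    "RmsfProfile",
    "PcaResult",
    "superpose",
    "apply_superposition",
    "rmsd_series",
    "rmsf_profile",
    "common_pca",
    "pc_span_area",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid-body fit: ``x' = rotation @ x + translation``."""

    rotation: np.ndarray       # (3, 3), proper orthonormal
    translation: np.ndarray    # (3,), nm
    rmsd_after: float          # nm


@dataclass(frozen=True)
class RmsdSeries:
    times: np.ndarray          # ps
    values: np.ndarray         # nm


@dataclass(frozen=True)
class RmsfProfile:
    residue_ids: np.ndarray    # author numbering, one per selected atom
    values: np.ndarray         # nm


@dataclass(frozen=True)
class PcaResult:
    """PCA of the pooled, superposed coordinate ensemble.

    ``components`` are orthonormal rows in the 3N coordinate space;
    ``eigenvalues`` (nm^2) are sorted descending; ``projections`` maps each
    trajectory label to its per-frame (PC1, PC2) coordinates.
    """

    mean_structure: np.ndarray          # (n_atoms, 3) nm
    components: np.ndarray              # (n_modes, 3*n_atoms)
    eigenvalues: np.ndarray             # (n_modes,) nm^2
    projections: dict[str, np.ndarray]  # label -> (n_frames, 2)


def _check_geometry(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise ValueError("superposition needs at least 3 atoms")
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-10 * max(s[0], 1.0):
        raise ValueError("degenerate geometry: reference atoms are collinear")


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Weighted Kabsch fit of ``mobile`` onto ``reference``.

    Returns the proper rotation (reflections corrected) and translation
    minimising the weighted RMSD, plus the residual RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have the same shape")
    _check_geometry(reference)
    w = np.ones(len(mobile)) if weights is None else np.asarray(weights, dtype=float)
    wn = w / w.sum()
    mob_c = (mobile * wn[:, None]).sum(axis=0)
    ref_c = (reference * wn[:, None]).sum(axis=0)
    a = mobile - mob_c
    b = reference - ref_c
    # align_vectors finds proper R minimising sum w |R a_i - b_i|^2
    rot, _ = Rotation.align_vectors(b, a, weights=w)
    R = rot.as_matrix()
    fitted = a @ R.T
    rmsd = float(np.sqrt((wn * ((fitted - b) ** 2).sum(axis=1)).sum()))
    return SuperpositionResult(rotation=R, translation=ref_c - R @ mob_c, rmsd_after=rmsd)


def apply_superposition(coords: np.ndarray, fit: SuperpositionResult) -> np.ndarray:
    return np.asarray(coords) @ fit.rotation.T + fit.translation


def rmsd_series(
    traj: Trajectory,
    sel: Selection,
    reference: Frame,
    mass_weighted: bool = True,
) -> RmsdSeries:
    """Per-frame RMSD (nm) after superposition onto a reference frame."""
    if len(sel) == 0:
        raise ValueError("RMSD over an empty selection is undefined")
    w = traj.topology.masses[sel.indices] if mass_weighted else None
    ref = reference.positions[sel.indices]
    values = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        values[i] = superpose(frame.positions[sel.indices], ref, w).rmsd_after
    return RmsdSeries(times=traj.times, values=values)


def _iterative_mean(coords: np.ndarray, weights: np.ndarray | None,
                    tol: float = 1e-6, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Superpose every frame onto the converged time-average structure.

    Returns (superposed coordinates, mean structure).  Starts from frame 0
    and re-superposes/re-averages until the mean shifts by less than
    ``tol`` (nm, RMS).
    """
    ref = coords[0]
    fitted = coords.copy()
    for _ in range(max_iter):
        for i in range(len(coords)):
            fitted[i] = apply_superposition(coords[i], superpose(coords[i], ref, weights))
        mean = fitted.mean(axis=0)
        shift = float(np.sqrt(((mean - ref) ** 2).sum(axis=1).mean()))
        ref = mean
        if shift < tol:
            break
    return fitted, ref


def rmsf_profile(traj: Trajectory, sel: Selection, mass_weighted: bool = True,
                 reference: str = "mean") -> RmsfProfile:
    """Root-mean-square fluctuation (nm) per selected atom.

    ``reference='mean'`` (default) superposes onto the iterated
    time-average structure; ``'first'`` uses frame 0 as a fixed reference.
    Entries are labelled by author residue id (one per selected atom; use a
    one-atom-per-residue selection such as ``name CA`` for a residue
    profile).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    if len(sel) == 0:
        raise ValueError("RMSF over an empty selection is undefined")
    coords = traj.coordinates(sel.indices)
    w = traj.topology.masses[sel.indices] if mass_weighted else None
    if reference == "mean":
        fitted, mean = _iterative_mean(coords, w)
    elif reference == "first":
        fitted = np.stack([
            apply_superposition(c, superpose(c, coords[0], w)) for c in coords
        ])
        mean = fitted.mean(axis=0)
    else:
        raise ValueError("reference must be 'mean' or 'first'")
    values = np.sqrt(((fitted - mean) ** 2).sum(axis=2).mean(axis=0))
    return RmsfProfile(residue_ids=traj.topology.resids[sel.indices].copy(), values=values)


def common_pca(
    trajs: list[Trajectory],
    selections: Selection | list[Selection],
    labels: list[str] | None = None,
    mass_weighted: bool = True,
) -> PcaResult:
    """PCA of the pooled, jointly superposed conformational ensemble.

    All frames from all trajectories are superposed onto the pooled mean
    structure; the covariance of the pooled 3N coordinate vectors is
    diagonalised once, and every trajectory is projected onto the shared
    eigenvectors — so the principal-component axes are common across
    trajectories and their spans are directly comparable.
    """
    if isinstance(selections, Selection):
        selections = [selections] * len(trajs)
    if len(selections) != len(trajs):
        raise ValueError("need one selection per trajectory")
    sizes = {len(s) for s in selections}
    if len(sizes) != 1:
        raise ValueError(f"selection sizes differ across trajectories: {sorted(sizes)}")
    n_atoms = sizes.pop()
    blocks = [t.coordinates(s.indices) for t, s in zip(trajs, selections)]
    pooled = np.concatenate(blocks, axis=0)
    if len(pooled) <= 3 * n_atoms:
        warnings.warn(
            f"pooled frame count {len(pooled)} <= 3 * n_atoms = {3 * n_atoms}; "
            "covariance will be rank-deficient"
        )
    w = trajs[0].topology.masses[selections[0].indices] if mass_weighted else None
    fitted, mean = _iterative_mean(pooled, w)
    x = (fitted - mean).reshape(len(fitted), 3 * n_atoms)
    cov = (x.T @ x) / len(x)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    comps = evecs[:, order].T
    if labels is None:
        labels = [f"traj{i}" for i in range(len(trajs))]
    projections = {}
    start = 0
    for label, block in zip(labels, blocks):
        seg = x[start : start + len(block)]
        projections[label] = seg @ comps[:2].T
        start += len(block)
    return PcaResult(mean_structure=mean, components=comps,
                     eigenvalues=evals, projections=projections)


def pc_span_area(points: np.ndarray) -> float:
    """Area (nm^2) of the 2-D convex hull of (PC1, PC2) projections.

    Fewer than 3 points, or collinear points, span zero area (warned).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must have shape (n, 2)")
    if len(points) < 3:
        warnings.warn("fewer than 3 projection points: span area is 0")
        return 0.0
    try:
        hull = ConvexHull(points)
    except QhullError:
        warnings.warn("projection points are collinear: span area is 0")
        return 0.0
    return float(hull.volume)  # in 2-D, ConvexHull.volume is the area
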
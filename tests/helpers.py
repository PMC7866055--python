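"""Shared independent oracles and ensemble builders for the test suite."""

import numpy as np


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def grid_oracle_min_rmsd(mobile, reference, weights=None, levels=24, n_per_level=300):
    """Exhaustive rotational-grid oracle: nested random-grid refinement.

    Searches rotation space directly (axis-angle perturbations with a
    geometrically shrinking radius); independent of the SVD/quaternion
    route used by the implementation.
    """
    w = np.ones(len(mobile)) if weights is None else np.asarray(weights, float)
    wn = w / w.sum()
    a = mobile - (mobile * wn[:, None]).sum(axis=0)
    b = reference - (reference * wn[:, None]).sum(axis=0)

    def rmsd_for(R):
        return np.sqrt((wn * (((a @ R.T) - b) ** 2).sum(axis=1)).sum())

    rng = np.random.default_rng(1234)
    best_R = np.eye(3)
    best = rmsd_for(best_R)
    scale = np.pi
    for _ in range(levels):
        axes = rng.normal(size=(n_per_level, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        angles = rng.uniform(-scale, scale, n_per_level)
        for axis, angle in zip(axes, angles):
            kx, ky, kz = axis
            K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
            R = (np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)) @ best_R
            r = rmsd_for(R)
            if r < best:
                best, best_R = r, R
        scale *= 0.55
    return best


def rigid_subspace(base):
    """Orthonormal basis (6, 3N) of rigid translations/rotations at ``base``."""
    n = len(base)
    centered = base - base.mean(axis=0)
    vecs = []
    for k in range(3):
        t = np.zeros((n, 3))
        t[:, k] = 1.0
        vecs.append(t.reshape(-1))
    for k in range(3):
        e = np.zeros(3)
        e[k] = 1.0
        vecs.append(np.cross(e, centered).reshape(-1))
    q, _ = np.linalg.qr(np.array(vecs).T)
    return q.T


def internal_modes(base, n_modes, rng):
    """Orthonormal displacement modes orthogonal to all rigid motions."""
    rigid = rigid_subspace(base)
    raw = rng.normal(size=(3 * len(base), n_modes))
    raw -= rigid.T @ (rigid @ raw)
    q, _ = np.linalg.qr(raw)
    return q.T  # (n_modes, 3N)


def three_mode_ensemble(rng, n_frames=5000, sds=(2.0, 1.0, 0.5)):
    """Gaussian ensemble with known variances along 3 internal modes.

    The base structure is large relative to the mode amplitudes so that
    superposition-induced nonlinearities stay well below the sampling
    error; modes are orthogonal to the rigid-body subspace by
    construction.
    """
    base = rng.normal(size=(4, 3)) * 30.0 + 200.0
    modes = internal_modes(base, 3, rng)
    sds = np.asarray(sds)
    frames = []
    for _ in range(n_frames):
        amp = rng.normal(size=3) * sds
        frames.append((base.reshape(-1) + amp @ modes).reshape(4, 3))
    return frames


def jarvis_hull_area(points):
    """Gift-wrapping convex hull + shoelace: independent of Qhull."""
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) < 3:
        return 0.0

    def cross2(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    start = min(range(len(pts)), key=lambda i: (pts[i, 0], pts[i, 1]))
    hull = [start]
    while True:
        p = hull[-1]
        q = (p + 1) % len(pts)
        for r in range(len(pts)):
            c = cross2(pts[p], pts[q], pts[r])
            if c < -1e-12 or (abs(c) < 1e-12 and
                              np.linalg.norm(pts[r] - pts[p]) >
                              np.linalg.norm(pts[q] - pts[p])):
                q = r
        if q == start:
            break
        hull.append(q)
        if len(hull) > len(pts):
            return 0.0
    poly = pts[hull]
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def flood_fill_touches_both_faces(mask):
    """Independent BFS flood fill (6-neighbour) over a boolean 3-D mask.

    Returns (touches_both_z_faces, n_components).
    """
    from collections import deque

    visited = np.zeros_like(mask, dtype=bool)
    nz = mask.shape[2]
    continuous = False
    n_components = 0
    for start in zip(*np.nonzero(mask & ~visited)):
        if visited[start]:
            continue
        n_components += 1
        lo = hi = start[2]
        queue = deque([start])
        visited[start] = True
        while queue:
            i, j, k = queue.popleft()
            lo, hi = min(lo, k), max(hi, k)
            for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                               (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                ni, nj, nk = i + di, j + dj, k + dk
                if (0 <= ni < mask.shape[0] and 0 <= nj < mask.shape[1]
                        and 0 <= nk < nz and mask[ni, nj, nk]
                        and not visited[ni, nj, nk]):
                    visited[ni, nj, nk] = True
                    queue.append((ni, nj, nk))
        if lo == 0 and hi == nz - 1:
            continuous = True
    return continuous, n_components
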
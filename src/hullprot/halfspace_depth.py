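"""Exact Tukey (half-space) depth of residues in 3-D.

The half-space depth of a point *x* with respect to a finite point set is the
minimum, over all closed half-spaces containing *x*, of the fraction of points
in that half-space.  The minimum is attained by a half-space whose boundary
plane passes through *x* and, generically, through two other points, so it
suffices to enumerate the normals of planes spanned by pairs of difference
vectors (plus the difference vectors themselves for collinear degeneracies).

For a candidate plane the achievable count is *not* simply the closed-side
count: the boundary can be tilted infinitesimally about a line through *x* so
that points lying exactly on the plane fall outside the half-space.  Which of
them can be tilted away is a 2-D sub-problem inside the plane — the minimum
over boundary lines through *x* of the points remaining on the closed side —
solved here by an exact angular sweep.  Points coincident with *x* can never
be excluded (the half-space is closed and contains *x*), which puts a floor
of (multiplicity of x)/N on the depth; in particular every hull vertex of a
duplicate-free set scores exactly 1/N.

Residue-level usage takes each residue's Cα as its representative point.
Exact cost is O(N³) per point; an approximate mode minimising over a fixed
quasi-uniform direction grid is provided for large chains.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List

import numpy as np

from .sasa_rsa import sphere_lattice
from .structure_model import ProteinStructure, ResidueKey

__all__ = ["HSDResult", "tukey_depth", "tukey_depth_all", "residue_hsd"]

_REL_TOL = 1e-9


@dataclasses.dataclass
class HSDResult:
    """Per-residue half-space depths (fractions in [1/N, 1])."""

    depth: Dict[ResidueKey, float]
    n_points: int
    representative: str = "CA"


def _min_halfplane_count(q2: np.ndarray, eps: float) -> int:
    """Minimum number of 2-D vectors inside a closed half-plane whose boundary
    passes through the origin.

    Exact angular sweep: the count of ``<q, w> >= 0`` as a function of the
    direction angle of ``w`` is piecewise constant with breakpoints at the
    vectors' angles ± 90°, so evaluating at every breakpoint and interval
    midpoint finds the minimum.  Near-zero projections count as inside
    (conservative for degenerate configurations)."""
    if len(q2) == 0:
        return 0
    ang = np.arctan2(q2[:, 1], q2[:, 0])
    crit = np.unique(np.concatenate([ang + np.pi / 2, ang - np.pi / 2]))
    crit = np.sort(np.mod(crit, 2 * np.pi))
    mids = (crit + np.roll(crit, -1)) / 2.0
    mids[-1] = (crit[-1] + crit[0] + 2 * np.pi) / 2.0
    phis = np.concatenate([crit, mids])
    w = np.column_stack([np.cos(phis), np.sin(phis)])
    counts = (q2 @ w.T >= -eps).sum(axis=0)
    return int(counts.min())


def _plane_basis(n: np.ndarray) -> np.ndarray:
    """Two orthonormal vectors spanning the plane with unit normal ``n``."""
    a = np.array([1.0, 0.0, 0.0])
    if abs(n[0]) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return np.vstack([e1, e2])


def tukey_depth(points: np.ndarray, index: int) -> float:
    """Exact Tukey depth of ``points[index]`` in the empirical distribution.

    Duplicate points are allowed and counted with multiplicity.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be (N, 3)")
    n = len(points)
    if n == 0:
        raise ValueError("empty point set")
    if not 0 <= index < n:
        raise IndexError(index)
    x = points[index]
    d = points - x
    scale = max(1.0, float(np.abs(d).max()))
    eps = _REL_TOL * scale
    dist = np.linalg.norm(d, axis=1)
    n_dup = int(np.count_nonzero(dist <= eps))  # includes the point itself
    others = d[dist > eps]
    m = len(others)
    if m == 0:
        return 1.0

    # candidate normals: all pairwise cross products (planes through x and
    # two other points) plus the difference vectors themselves
    cand_list = [others]
    pair_generated = [np.zeros(m, dtype=bool)]
    if m >= 2:
        iu, ju = np.triu_indices(m, k=1)
        cand_list.append(np.cross(others[iu], others[ju]))
        pair_generated.append(np.ones(len(iu), dtype=bool))
    cand = np.vstack(cand_list)
    is_pair = np.concatenate(pair_generated)
    norms = np.linalg.norm(cand, axis=1)
    keep = norms > eps
    cand = cand[keep] / norms[keep, None]
    is_pair = is_pair[keep]

    best = m
    chunk = max(1, int(4e6 // max(1, m)))
    for start in range(0, len(cand), chunk):
        normals = cand[start: start + chunk]
        s = normals @ others.T
        below = np.count_nonzero(s < -eps, axis=1)
        above = np.count_nonzero(s > eps, axis=1)
        on = m - below - above
        base = np.minimum(below, above)
        # a pair plane with exactly its two generating (non-collinear) points
        # on it can always be tilted so both fall outside the half-space
        free = (on == 0) | (is_pair[start: start + chunk] & (on == 2))
        if free.any():
            best = min(best, int(base[free].min()))
        # degenerate candidates: solve the in-plane sweep exactly
        for idx in np.flatnonzero(~free):
            if base[idx] >= best:
                continue
            n_vec = normals[idx]
            on_pts = others[np.abs(s[idx]) <= eps]
            t = _min_halfplane_count(on_pts @ _plane_basis(n_vec).T, eps)
            best = min(best, int(base[idx]) + t)
    return (best + n_dup) / n


def tukey_depth_all(points: np.ndarray) -> np.ndarray:
    """Exact Tukey depth of every point (vector of fractions)."""
    points = np.asarray(points, dtype=float)
    return np.array([tukey_depth(points, i) for i in range(len(points))])


def _approx_depth_all(points: np.ndarray, n_directions: int) -> np.ndarray:
    """Upper-bound depth from a fixed quasi-uniform direction grid.

    Never below the exact value; converges to it as the grid densifies.
    """
    dirs = sphere_lattice(n_directions)
    proj = points @ dirs.T  # (N, D)
    n = len(points)
    depths = np.empty(n)
    eps = _REL_TOL * max(1.0, float(np.abs(proj).max()))
    for i in range(n):
        below = np.count_nonzero(proj < proj[i] - eps, axis=0)
        above = np.count_nonzero(proj > proj[i] + eps, axis=0)
        on = n - below - above
        depths[i] = (np.minimum(below, above) + on).min() / n
    return depths


def residue_hsd(
    structure: ProteinStructure,
    exact: bool = True,
    n_directions: int = 2000,
) -> HSDResult:
    """Half-space depth of every residue's Cα against the chain's Cα cloud.

    Residues lacking a Cα are excluded (N reduced accordingly).  ``exact``
    switches between the plane-enumeration algorithm and the direction-grid
    approximation.
    """
    keys: List[ResidueKey] = []
    coords: List[np.ndarray] = []
    for res in structure:
        a = res.atom("CA")
        if a is not None:
            keys.append(res.key)
            coords.append(a.coord)
    if len(keys) < 4:
        raise ValueError(f"need >= 4 residues with Cα, got {len(keys)}")
    pts = np.array(coords)
    depths = tukey_depth_all(pts) if exact else _approx_depth_all(pts, n_directions)
    return HSDResult(depth=dict(zip(keys, depths.tolist())), n_points=len(keys))
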
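"""Convex-hull peeling of the exposed-atom point set into onion layers.

The exposed atoms of a protein (all atoms of residues with RSA > 0, pooled
over the selected chains) form a point set X.  Atoms on the convex hull
surface of X are layer 1, CH₁(X); peeling them off and re-hulling the
remainder gives CH₂(X), and so on until X is exhausted — the layers partition
X.  A residue's hull level is the *minimum* level among its atoms (a residue
whose atom levels are {2, 3, 3, 5} sits at level 2).  The cumulate hull
CHᵏ(X) is the union of layers 1..k, and K₀ is the smallest k whose cumulate
hull contains every epitope residue.

Conventions: hulls are computed on atom centres; points lying on a hull facet
without being vertices are removed with the current layer (within a 1e-9
relative tolerance) so coplanar patches cannot stall the peel; degenerate
remainders (≤ 4 points, coplanar or collinear sets) are assigned wholesale to
the current layer; duplicate coordinates collapse to one point for the hull
and share its level.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .sasa_rsa import ResidueRSA
from .structure_model import EpitopeAnnotation, ProteinStructure, ResidueKey

__all__ = [
    "HullDecomposition",
    "K0Result",
    "convex_hull_peel",
    "residue_hull_levels",
    "cumulate_membership",
    "compute_k0",
]

_REL_TOL = 1e-9


@dataclasses.dataclass
class HullDecomposition:
    """Levels assigned by peeling: per peeled atom and per exposed residue."""

    atom_level: np.ndarray  # level per point of X, in input order
    residue_level: Dict[ResidueKey, int]
    n_levels: int
    X_size: int

    def layer_sizes(self) -> Dict[int, int]:
        vals, counts = np.unique(self.atom_level, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


@dataclasses.dataclass
class K0Result:
    """Smallest k such that CHᵏ(X) contains every epitope residue."""

    k0: int
    n_epitopes: int


def convex_hull_peel(points: Sequence[Sequence[float]] | np.ndarray) -> np.ndarray:
    """Assign a peel level (1-based) to every input point.

    Returns an integer array aligned with the input order.  Duplicate
    coordinates receive the level of their shared location.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be (N, 3)")
    if len(pts) == 0:
        raise ValueError("empty point set")

    uniq, inverse = np.unique(pts, axis=0, return_inverse=True)
    uniq_level = np.zeros(len(uniq), dtype=int)
    remaining = np.arange(len(uniq))
    scale = max(1.0, float(np.abs(uniq).max()))
    tol = _REL_TOL * scale

    level = 0
    while len(remaining) > 0:
        level += 1
        sub = uniq[remaining]
        on_surface = _hull_surface_mask(sub, tol)
        uniq_level[remaining[on_surface]] = level
        remaining = remaining[~on_surface]
    return uniq_level[inverse]


def _hull_surface_mask(pts: np.ndarray, tol: float) -> np.ndarray:
    """True for points on the convex hull surface of ``pts``.

    Degenerate sets (too few points, coplanar, collinear) are entirely "on
    the surface" by contract, which guarantees the peel terminates.
    """
    if len(pts) <= 4:
        return np.ones(len(pts), dtype=bool)
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return np.ones(len(pts), dtype=bool)
    # signed distance to the closest facet plane: 0 (within tol) = on surface
    dist = pts @ hull.equations[:, :3].T + hull.equations[:, 3]
    on = dist.max(axis=1) >= -tol
    on[hull.vertices] = True
    return on


def residue_hull_levels(
    structure: ProteinStructure,
    exposure: ResidueRSA,
) -> HullDecomposition:
    """Peel the exposed-atom set and assign each exposed residue the minimum
    of its atoms' levels.

    X pools every atom of every exposed residue (RSA > 0) across the selected
    chains, matching how multi-chain complexes are treated.
    """
    exposed_res = [res for res in structure if exposure.exposed.get(res.key, False)]
    if not exposed_res:
        raise ValueError("no exposed residues (RSA > 0)")
    coords: List[np.ndarray] = []
    owners: List[ResidueKey] = []
    for res in exposed_res:
        for atom in res.atoms:
            coords.append(atom.coord)
            owners.append(res.key)
    X = np.array(coords)
    atom_level = convex_hull_peel(X)
    residue_level: Dict[ResidueKey, int] = {}
    for key, lvl in zip(owners, atom_level.tolist()):
        cur = residue_level.get(key)
        if cur is None or lvl < cur:
            residue_level[key] = lvl
    return HullDecomposition(
        atom_level=atom_level,
        residue_level=residue_level,
        n_levels=int(atom_level.max()),
        X_size=len(X),
    )


def cumulate_membership(decomp: HullDecomposition, k: int) -> Dict[ResidueKey, bool]:
    """Flag each exposed residue as a member of the cumulate hull CHᵏ(X)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return {key: lvl <= k for key, lvl in decomp.residue_level.items()}


def compute_k0(decomp: HullDecomposition, labels: EpitopeAnnotation) -> K0Result:
    """K₀ = max hull level over the epitope residues of this protein."""
    levels = [
        lvl for key, lvl in decomp.residue_level.items() if labels.is_epitope(key)
    ]
    if not levels:
        raise ValueError("no epitope residues among the exposed set; K0 undefined")
    return K0Result(k0=max(levels), n_epitopes=len(levels))
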
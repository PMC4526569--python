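"""Residue depth descriptors: Chakravarty-style depth, DPX, half-sphere exposure.

Three complementary measures of how deeply a residue sits in the protein:

* **Chakravarty depth** — distance of each atom to the nearest solvent-surface
  point, averaged over the residue's heavy atoms.  The classical definition
  uses the nearest surface *water* of a solvated model; here the retained
  solvent-accessible sample points of the ASA calculation serve as the surface
  proxy, a documented approximation that shifts absolute values by a fraction
  of an Å at most.  A reader for ``depth-1.0`` output is provided for exact
  parity with the original program.
* **DPX** — 0 for any solvent-accessible atom (ASA > 0); for a buried atom the
  distance to the nearest accessible atom centre; averaged per residue.
* **HSE** — counts of other residues' Cα atoms in the up/down half-spheres of
  radius 13 Å around a residue's Cα.  Mode A orients the dividing plane with
  the pseudo-Cβ vector built from the chain neighbours' Cα positions; mode B
  uses the actual Cα→Cβ vector (falling back to the mode-A vector for Gly or
  a missing Cβ).  Neighbours exactly on the dividing plane count as *down*.
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .sasa_rsa import AtomSASA
from .structure_model import ProteinStructure, ResidueKey

__all__ = [
    "chakravarty_depth",
    "dpx",
    "half_sphere_exposure",
    "read_depth_output",
    "read_dpx_output",
]


def chakravarty_depth(structure: ProteinStructure, sasa: AtomSASA) -> Dict[ResidueKey, float]:
    """Mean distance of each residue's atoms to the nearest surface point (Å).

    ``sasa`` must have been computed with ``keep_samples=True``.
    """
    if sasa.surface_samples is None:
        raise ValueError("atom_sasa must be run with keep_samples=True")
    if len(sasa.surface_samples) == 0:
        raise ValueError("no solvent-accessible surface points (fully occluded input)")
    tree = cKDTree(sasa.surface_samples)
    coords = structure.atom_coords()
    atom_depth, _ = tree.query(coords)
    depths: Dict[ResidueKey, float] = {}
    idx = 0
    for res in structure:
        n = len(res.atoms)
        depths[res.key] = float(atom_depth[idx: idx + n].mean())
        idx += n
    return depths


def dpx(structure: ProteinStructure, sasa: AtomSASA) -> Dict[ResidueKey, float]:
    """Mean atom DPX per residue (Å).

    Atom DPX is zero for solvent-accessible atoms (ASA > 0) and the distance
    to the nearest accessible atom centre for buried ones.
    """
    coords = structure.atom_coords()
    accessible = sasa.asa > 0.0
    if not accessible.any():
        raise ValueError("no solvent-accessible atoms")
    atom_dpx = np.zeros(len(coords))
    buried = ~accessible
    if buried.any():
        tree = cKDTree(coords[accessible])
        atom_dpx[buried], _ = tree.query(coords[buried])
    depths: Dict[ResidueKey, float] = {}
    idx = 0
    for res in structure:
        n = len(res.atoms)
        depths[res.key] = float(atom_dpx[idx: idx + n].mean())
        idx += n
    return depths


def _mode_a_vectors(structure: ProteinStructure) -> Dict[ResidueKey, Optional[np.ndarray]]:
    """Pseudo-Cβ direction per residue: (Cα_i − Cα_{i−1}) + (Cα_i − Cα_{i+1}).

    Terminal residues use the single available neighbour; an isolated residue
    (chain of length 1) gets ``None`` with a warning.
    """
    vectors: Dict[ResidueKey, Optional[np.ndarray]] = {}
    for chain_id in structure.chain_ids:
        chain = [r for r in structure.chain(chain_id) if r.atom("CA") is not None]
        for i, res in enumerate(chain):
            ca = res.atom("CA").coord
            parts = []
            if i > 0:
                prev = chain[i - 1].atom("CA").coord
                parts.append(ca - prev)
            if i + 1 < len(chain):
                nxt = chain[i + 1].atom("CA").coord
                parts.append(ca - nxt)
            if not parts:
                warnings.warn(f"chain {chain_id!r} has a single Cα; HSE up-sphere undefined")
                vectors[res.key] = None
            else:
                vectors[res.key] = np.sum(parts, axis=0)
    return vectors


def half_sphere_exposure(
    structure: ProteinStructure,
    radius: float = 13.0,
    mode: str = "A",
) -> Dict[ResidueKey, Tuple[int, int]]:
    """(up, down) Cα neighbour counts within ``radius`` Å of each residue's Cα.

    Neighbours are all *other* residues' Cα atoms in the structure (across
    chains).  ``up`` counts strictly positive projections on the side-chain
    direction; zero projections fall in ``down``.  Residues without a Cα are
    skipped.
    """
    if mode not in ("A", "B"):
        raise ValueError("mode must be 'A' or 'B'")
    keys = []
    ca = []
    for res in structure:
        a = res.atom("CA")
        if a is not None:
            keys.append(res.key)
            ca.append(a.coord)
    ca_arr = np.array(ca)
    mode_a = _mode_a_vectors(structure)
    tree = cKDTree(ca_arr)

    result: Dict[ResidueKey, Tuple[int, int]] = {}
    for i, key in enumerate(keys):
        neigh = [j for j in tree.query_ball_point(ca_arr[i], radius) if j != i]
        u = mode_a.get(key)
        if mode == "B":
            res = structure[key]
            cb = res.atom("CB")
            if cb is not None:
                u = cb.coord - res.atom("CA").coord
        if u is None or not neigh:
            result[key] = (0, len(neigh))
            continue
        rel = ca_arr[neigh] - ca_arr[i]
        up = int(np.count_nonzero(rel @ u > 0.0))
        result[key] = (up, len(neigh) - up)
    return result


def read_depth_output(path: str) -> Dict[ResidueKey, float]:
    """Read per-residue depths from a ``depth-1.0`` ``*-residue.depth`` file.

    Expected whitespace layout per data line:
    ``chain:resnum restype depth_all_atoms ...`` — only the first depth column
    is used.  Substitutes the computed Chakravarty column bit-for-bit.
    """
    out: Dict[ResidueKey, float] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 3 or parts[0].lower().startswith(("#", "chain")):
                continue
            chain, _, num = parts[0].partition(":")
            if not num:
                continue
            try:
                seq = int(num)
                depth = float(parts[2])
            except ValueError:
                continue
            out[(chain, seq, "")] = depth
    if not out:
        raise ValueError(f"{path}: no residue depth records recognised")
    return out


def read_dpx_output(path: str) -> Dict[ResidueKey, float]:
    """Read per-residue mean DPX from the original DPX program's output.

    Expected whitespace layout per data line: ``chain resnum restype dpx``.
    """
    out: Dict[ResidueKey, float] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 4 or parts[0].startswith("#"):
                continue
            try:
                seq = int(parts[1])
                val = float(parts[3])
            except ValueError:
                continue
            out[(parts[0], seq, "")] = val
    if not out:
        raise ValueError(f"{path}: no DPX records recognised")
    return out
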
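"""Deterministic synthetic inputs: shell clouds, mini-PDBs, globules, WOP files.

Everything here regenerates byte-identically from a spec + seed: geometry
comes from deterministic lattices (no RNG), randomness is confined to labels
and globule packing and always flows through a seeded generator.  The shell
cloud is the ground-truth test bed for hull peeling (its true peel level is
the shell index); the globule emulates a compact single-domain antigen at
protein-like packing density with surface-enriched epitope labels; the
mini-PDB writer turns small residue tables into parseable ATOM records.

These generators emulate geometry and labelling only — no physics, no
side-chain chemistry — so tests built on them probe the feature algorithms,
not biological realism.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .sasa_rsa import sphere_lattice
from .structure_model import Atom, EpitopeAnnotation, ProteinStructure, Residue, ResidueKey

__all__ = [
    "ShellCloud",
    "make_shell_cloud",
    "make_mini_pdb",
    "extended_peptide_spec",
    "make_globule",
    "structure_from_points",
    "make_wop_fixture",
]


@dataclasses.dataclass
class ShellCloud:
    """Labelled point cloud on concentric spheres with known peel levels."""

    points: np.ndarray          # (n, 3)
    true_level: np.ndarray      # shell index from outermost, 1-based
    epitope: np.ndarray         # boolean labels
    radii: Tuple[float, ...]


def _shell_spacing(radius: float, n_points: int) -> float:
    """Approximate nearest-neighbour spacing of a quasi-uniform spherical
    lattice: sqrt(sphere area per point)."""
    return math.sqrt(4.0 * math.pi * radius * radius / n_points)


def make_shell_cloud(
    n_shells: int,
    pts_per_shell: int,
    radii: Sequence[float],
    epitope_fraction_by_shell: Sequence[float],
    seed: int,
) -> ShellCloud:
    """Concentric spherical shells with per-shell epitope label fractions.

    ``radii`` are given outermost-first and must be separated by more than the
    lattice point spacing so the peel order is unambiguous.  Level ground
    truth: shell 1 (largest radius) peels first.
    """
    if n_shells < 1 or pts_per_shell < 20:
        raise ValueError("need n_shells >= 1 and pts_per_shell >= 20")
    radii = tuple(float(r) for r in radii)
    if len(radii) != n_shells or len(epitope_fraction_by_shell) != n_shells:
        raise ValueError("radii and epitope fractions must match n_shells")
    if sorted(radii, reverse=True) != list(radii):
        raise ValueError("radii must be strictly decreasing (outermost first)")
    for outer, inner in zip(radii, radii[1:]):
        spacing = max(_shell_spacing(outer, pts_per_shell), _shell_spacing(inner, pts_per_shell))
        if outer - inner <= spacing:
            raise ValueError(
                f"shells at radii {outer} and {inner} overlap: gap {outer - inner:.2f} "
                f"<= point spacing {spacing:.2f}"
            )

    rng = np.random.default_rng(seed)
    base = sphere_lattice(pts_per_shell)
    points: List[np.ndarray] = []
    levels: List[np.ndarray] = []
    labels: List[np.ndarray] = []
    for i, (r, frac) in enumerate(zip(radii, epitope_fraction_by_shell), start=1):
        # deterministic per-shell rotation so shells are not radially aligned
        theta = 0.61803398875 * i * 2.0 * math.pi
        rot = np.array(
            [
                [math.cos(theta), -math.sin(theta), 0.0],
                [math.sin(theta), math.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        points.append(r * base @ rot.T)
        levels.append(np.full(pts_per_shell, i, dtype=int))
        labels.append(rng.random(pts_per_shell) < frac)
    return ShellCloud(
        points=np.vstack(points),
        true_level=np.concatenate(levels),
        epitope=np.concatenate(labels),
        radii=radii,
    )


def make_mini_pdb(spec: Sequence[dict]) -> str:
    """Render a residue/coordinate table as PDB ATOM records.

    Each entry: ``{"chain", "seq_num", "aa3", "atoms": [(name, element, x, y, z)]}``.
    Occupancy 1.0, B-factor 0.0; LF line endings.
    """
    lines: List[str] = []
    serial = 0
    for res in spec:
        atoms = res.get("atoms")
        if not atoms:
            raise ValueError(f"residue {res} has no atoms")
        for name, element, x, y, z in atoms:
            serial += 1
            if not name or not element:
                raise ValueError(f"bad atom spec {name!r}/{element!r}")
            pname = name if len(name) == 4 else f" {name:<3s}"
            lines.append(
                f"ATOM  {serial:>5d} {pname:<4.4s} {res['aa3']:>3s} "
                f"{res['chain']:1s}{res['seq_num']:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


_BACKBONE_OFFSETS = [
    # crude extended-conformation offsets from the residue origin (Å)
    ("N", "N", (-1.20, 0.30, 0.0)),
    ("CA", "C", (0.0, 0.0, 0.0)),
    ("C", "C", (1.25, 0.60, 0.0)),
    ("O", "O", (1.30, 1.85, 0.0)),
]


def extended_peptide_spec(aa3_list: Sequence[str], chain: str = "A") -> List[dict]:
    """Residue table for a straight pseudo-extended peptide (3.8 Å Cα steps).

    Non-Gly residues get a Cβ.  Geometry is schematic, not stereochemical —
    sufficient for parser, SASA and peel tests.
    """
    spec: List[dict] = []
    for i, aa3 in enumerate(aa3_list):
        cx = 3.8 * i
        atoms = [(n, e, cx + dx, dy, dz) for n, e, (dx, dy, dz) in _BACKBONE_OFFSETS]
        if aa3 != "GLY":
            atoms.append(("CB", "C", cx, -0.77, 1.25))
        spec.append({"chain": chain, "seq_num": i + 1, "aa3": aa3, "atoms": atoms})
    return spec


def structure_from_points(
    points: np.ndarray,
    chain_id: str = "A",
    pdb_id: str = "SYNT",
    sphere_radius: float = 1.70,
) -> ProteinStructure:
    """Wrap a point cloud as a Cα-only poly-alanine pseudo-protein.

    ``sphere_radius`` overrides the per-atom vdW radius; a residue-sized value
    (~3 Å) turns the cloud into a coarse-grained model whose interior is
    genuinely solvent-excluded.
    """
    residues = []
    for i, p in enumerate(np.asarray(points, dtype=float), start=1):
        res = Residue(chain_id=chain_id, seq_num=i, icode="", aa3="ALA", aa1="A")
        res.atoms.append(
            Atom(
                serial=i, name="CA", element="C", coord=p, vdw_radius=sphere_radius,
                residue_key=res.key,
            )
        )
        residues.append(res)
    return ProteinStructure(pdb_id=pdb_id, residues=residues)


def make_globule(
    n_residues: int = 150,
    seed: int = 0,
    min_dist: float = 3.8,
    epitope_fraction_outer: float = 0.25,
    epitope_fraction_inner: float = 0.03,
    sphere_radius: float = 3.0,
) -> Tuple[ProteinStructure, EpitopeAnnotation]:
    """Compact Cα-only pseudo-antigen with surface-enriched epitope labels.

    Points are rejection-packed in a ball at protein-like Cα density
    (~3.8 Å minimum separation) and modelled as residue-sized spheres
    (``sphere_radius`` ≈ 3 Å) so the core is solvent-excluded; residues in the
    outer radial half draw the epitope label at ``epitope_fraction_outer``,
    the rest at ``epitope_fraction_inner`` — mirroring the empirical surface
    preference of conformational epitopes without modelling antibody contacts.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    rng = np.random.default_rng(seed)
    # ball radius for protein-like packing: volume per residue ~ (1.3*min_dist)^3
    radius = (n_residues * (1.3 * min_dist) ** 3 * 3.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    pts: List[np.ndarray] = []
    attempts = 0
    while len(pts) < n_residues:
        attempts += 1
        if attempts > 200 * n_residues:
            raise RuntimeError("packing failed; lower the density")
        p = rng.uniform(-radius, radius, 3)
        if np.linalg.norm(p) > radius:
            continue
        if pts and np.min(np.linalg.norm(np.array(pts) - p, axis=1)) < min_dist:
            continue
        pts.append(p)
    points = np.array(pts)
    structure = structure_from_points(points, pdb_id=f"GLOB{seed}", sphere_radius=sphere_radius)
    r = np.linalg.norm(points, axis=1)
    outer = r > np.median(r)
    frac = np.where(outer, epitope_fraction_outer, epitope_fraction_inner)
    is_epi = rng.random(n_residues) < frac
    labels = {
        res.key: bool(flag) for res, flag in zip(structure, is_epi)
    }
    return structure, EpitopeAnnotation(labels)


def make_dssp_fixture(records: Sequence[Tuple[str, int, str, str, str]]) -> str:
    """Synthetic classic-format DSSP text for parser tests.

    ``records``: (chain, resseq, icode, aa1, ss8) per residue.  Only the
    fields the residue-record parser reads are populated (index, residue id,
    amino acid, secondary-structure code, zeroed accessibility/H-bond/angle
    columns); everything else is padding.
    """
    lines = [
        "==== Secondary Structure Definition (synthetic fixture) ====",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    "
        "N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA",
    ]
    for i, (chain, resseq, icode, aa1, ss8) in enumerate(records, start=1):
        buf = [" "] * 120

        def put(text: str, start: int, end: int) -> None:
            buf[start:end] = f"{text:>{end - start}}"[: end - start]

        put(str(i), 0, 5)
        put(str(resseq), 5, 10)
        buf[10] = (icode or " ")[0]
        buf[11] = chain[0]
        buf[13] = aa1[0]
        buf[16] = (ss8 or " ")[0]
        put("0", 34, 38)                     # ACC
        for s, e in ((38, 45), (50, 56), (61, 67), (72, 78)):
            put("0", s, e)                   # H-bond partner indices
        for s, e in ((46, 50), (57, 61), (68, 72), (79, 83)):
            put("0.0", s, e)                 # H-bond energies
        put("360.0", 103, 109)               # phi
        put("360.0", 109, 115)               # psi
        lines.append("".join(buf))
    return "\n".join(lines) + "\n"


_WOP_HEADER = (
    "\n"
    "Last position-specific scoring matrix computed, weighted observed percentages rounded down,\n"
    "information per position, and relative weight of gapless real matches to pseudocounts\n"
    "            A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V"
    "    A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V\n"
)

_PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"


def make_wop_fixture(n_positions: int, profile: str = "mixed") -> str:
    """PSI-BLAST-style ASCII PSSM text realising simple WOP profiles.

    Profiles: ``zeros`` (no alignment information → conservation 1),
    ``uniform`` (all 5% → conservation 0), ``single`` (100% own residue →
    conservation 1), ``mixed`` (cycles through the three).
    """
    if profile not in ("zeros", "uniform", "single", "mixed"):
        raise ValueError(f"unknown profile {profile!r}")
    kinds = {"zeros": ["zeros"], "uniform": ["uniform"], "single": ["single"],
             "mixed": ["zeros", "uniform", "single"]}[profile]
    lines = [_WOP_HEADER.rstrip("\n")]
    for i in range(n_positions):
        kind = kinds[i % len(kinds)]
        aa = _PSIBLAST_ORDER[i % 20]
        if kind == "zeros":
            wop = [0] * 20
        elif kind == "uniform":
            wop = [5] * 20
        else:
            wop = [0] * 20
            wop[_PSIBLAST_ORDER.index(aa)] = 100
        logodds = "  0" * 20
        wop_txt = "".join(f"{v:>4d}" for v in wop)
        lines.append(f"{i + 1:>5d} {aa}{logodds}{wop_txt}  0.00 0.00")
    lines.append("")
    lines.append("                      K         Lambda")
    lines.append("Standard Ungapped    0.1337     0.3190")
    return "\n".join(lines) + "\n"
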
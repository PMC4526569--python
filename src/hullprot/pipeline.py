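"""End-to-end feature computation: structure → per-residue feature table.

Chains one pass of the whole stack — SASA/RSA, Chakravarty-style depth, DPX,
the four HSE counts, half-space depth, hull peel level — into a single
pandas DataFrame with one row per residue, which is what the CLI writes and
the cohort statistics consume.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import depth_functions, halfspace_depth, hull_peeling, sasa_rsa
from .structure_model import EpitopeAnnotation, ProteinStructure

__all__ = ["FeatureConfig", "compute_features"]


@dataclasses.dataclass
class FeatureConfig:
    """Knobs of one feature run; defaults reproduce the standard analysis."""

    probe_radius: float = 1.4      # Å, water probe
    n_points: int = 960            # SASA sample points per atom
    hse_radius: float = 13.0       # Å, half-sphere neighbour radius
    hsd_exact: bool = True         # exact Tukey depth vs direction-grid bound
    hsd_directions: int = 2000     # grid size for the approximate mode

    def as_dict(self) -> Dict[str, object]:
        return dataclasses.asdict(self)


def compute_features(
    structure: ProteinStructure,
    labels: Optional[EpitopeAnnotation] = None,
    config: Optional[FeatureConfig] = None,
) -> pd.DataFrame:
    """Compute every per-residue feature for one structure.

    Returns a DataFrame indexed 0..n-1 with residue identity columns
    (chain, seq_num, icode, aa3, aa1) and feature columns (asa, rsa, exposed,
    chakravarty, dpx, hseau/hsead/hsebu/hsebd, hsd, hull_level, epitope).
    ``hull_level`` and ``hsd`` are NaN for residues outside their input sets
    (buried residues / residues without a Cα).
    """
    cfg = config or FeatureConfig()
    sasa = sasa_rsa.atom_sasa(
        structure, probe=cfg.probe_radius, n_points=cfg.n_points, keep_samples=True
    )
    rsa = sasa_rsa.residue_rsa(sasa, structure)
    chak = depth_functions.chakravarty_depth(structure, sasa)
    dpx_vals = depth_functions.dpx(structure, sasa)
    hse_a = depth_functions.half_sphere_exposure(structure, radius=cfg.hse_radius, mode="A")
    hse_b = depth_functions.half_sphere_exposure(structure, radius=cfg.hse_radius, mode="B")
    try:
        hsd = halfspace_depth.residue_hsd(
            structure, exact=cfg.hsd_exact, n_directions=cfg.hsd_directions
        ).depth
    except ValueError:
        hsd = {}
    try:
        decomp = hull_peeling.residue_hull_levels(structure, rsa)
        levels = decomp.residue_level
    except ValueError:
        levels = {}

    rows = []
    for res in structure:
        key = res.key
        up_a, down_a = hse_a.get(key, (np.nan, np.nan))
        up_b, down_b = hse_b.get(key, (np.nan, np.nan))
        rows.append(
            {
                "chain": res.chain_id,
                "seq_num": res.seq_num,
                "icode": res.icode,
                "aa3": res.aa3,
                "aa1": res.aa1,
                "asa": rsa.asa[key],
                "rsa": rsa.rsa[key],
                "exposed": rsa.exposed[key],
                "chakravarty": chak[key],
                "dpx": dpx_vals[key],
                "hseau": up_a,
                "hsead": down_a,
                "hsebu": up_b,
                "hsebd": down_b,
                "hsd": hsd.get(key, np.nan),
                "hull_level": levels.get(key, np.nan),
                "epitope": labels.is_epitope(key) if labels else False,
            }
        )
    return pd.DataFrame(rows)
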
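"""Sequence-derived features: conservation, secondary structure, composition.

Conservation follows an entropy complement over PSI-BLAST weighted observation
percentages (WOP): with p_k the WOP entry divided by 100,

    conservation = 1 − ( −Σ_k p_k·log₂ p_k ) / log₂ 20

0·log 0 is taken as 0, the p_k are used exactly as given (no renormalisation),
and an all-zero WOP row — PSI-BLAST's signature for positions with no
alignment information — scores 1 by convention.

DSSP output files are parsed (never executed) and the eight-state codes are
grouped into three classes: H/G/I → helix, E/B → strand, everything else →
coil.  Amino-acid composition is the per-type residue count divided by the
protein length.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, Iterable, List, Tuple

import numpy as np
from Bio.PDB.DSSP import make_dssp_dict

from .structure_model import ResidueKey

__all__ = [
    "AA_ORDER",
    "PSIBLAST_AA_ORDER",
    "conservation",
    "parse_wop",
    "map_ss8_to_ss3",
    "parse_dssp",
    "aa_composition",
]

#: Alphabetical one-letter order used for composition vectors.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

#: Column order of the 20 WOP columns in PSI-BLAST ASCII PSSM files.
PSIBLAST_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

_LOG2_20 = math.log2(20.0)


def conservation(wop_row: Iterable[float]) -> float:
    """Entropy-complement conservation score from one 20-entry WOP row."""
    row = np.asarray(list(wop_row), dtype=float)
    if row.shape != (20,):
        raise ValueError("WOP row must have 20 entries")
    if (row < 0).any():
        raise ValueError("WOP entries must be non-negative")
    p = row / 100.0
    if not p.any():
        return 1.0
    nz = p[p > 0]
    entropy = -(nz * np.log2(nz)).sum()
    return float(1.0 - entropy / _LOG2_20)


def parse_wop(path: str | Path) -> Tuple[np.ndarray, str]:
    """Read the WOP block of a PSI-BLAST ASCII PSSM (``-Q`` output).

    Data lines carry: position, residue letter, 20 log-odds scores, 20 WOP
    percentages, information content, gapless match weight.  Returns the
    (n_positions, 20) WOP matrix in PSI-BLAST column order plus the query
    sequence.

    Raises ``ValueError`` with the offending line number on malformed input.
    """
    rows: List[List[float]] = []
    seq: List[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            parts = raw.split()
            if len(parts) < 2 or not parts[0].isdigit():
                continue  # header / footer noise
            if not (len(parts[1]) == 1 and parts[1].isalpha()):
                continue
            if len(parts) < 42:
                raise ValueError(f"{path}:{lineno}: truncated PSSM row ({len(parts)} fields)")
            try:
                wop = [float(v) for v in parts[22:42]]
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric WOP entry") from None
            rows.append(wop)
            seq.append(parts[1].upper())
    if not rows:
        raise ValueError(f"{path}: no PSSM data rows found")
    return np.array(rows), "".join(seq)


def map_ss8_to_ss3(code8: str) -> str:
    """Collapse an eight-state DSSP code to helix / strand / coil."""
    c = (code8 or " ").upper()
    if c in ("H", "G", "I"):
        return "helix"
    if c in ("E", "B"):
        return "strand"
    return "coil"


def parse_dssp(path: str | Path) -> Dict[ResidueKey, Tuple[str, str]]:
    """Read a DSSP output file → ``{residue key: (ss8, ss3)}``.

    Residues are matched downstream by (chain, seq_num, icode).
    """
    dssp_dict, _ = make_dssp_dict(str(path))
    out: Dict[ResidueKey, Tuple[str, str]] = {}
    for (chain, res_id), values in dssp_dict.items():
        _, seq_num, icode = res_id
        ss8 = values[1]
        out[(chain, seq_num, icode.strip())] = (ss8, map_ss8_to_ss3(ss8))
    return out


def aa_composition(aa_letters: Iterable[str], protein_length: int) -> Dict[str, float]:
    """Per-type counts of a residue group divided by the protein length.

    ``aa_letters`` holds the one-letter codes of the group (e.g. the epitope
    residues of one antigen); non-standard letters ('X') are ignored.
    """
    if protein_length <= 0:
        raise ValueError("protein_length must be positive")
    comp = {aa: 0.0 for aa in AA_ORDER}
    for aa in aa_letters:
        if aa in comp:
            comp[aa] += 1.0
    return {aa: count / protein_length for aa, count in comp.items()}
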
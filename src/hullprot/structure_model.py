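"""Atom/residue data model for antigen structures.

Parses PDB files into a lightweight atom/residue hierarchy suitable for the
geometric feature stack (solvent accessibility, depth functions, convex-hull
peeling), and attaches per-residue epitope labels from a plain-text annotation
file.  Parsing is delegated to :mod:`gemmi`; the model kept here is deliberately
minimal — coordinates, elements, van der Waals radii and residue grouping are
all the downstream geometry needs.

Conventions applied on load:

* hydrogens (and deuterium) are dropped — every depth function here is defined
  on heavy atoms;
* waters are always dropped, other HETATM groups only kept on request;
* for alternate locations, the highest-occupancy conformer is kept (ties break
  toward the first occurrence in the file);
* van der Waals radii come from a fixed element table (NACCESS-compatible:
  C 1.70, N 1.55, O 1.52, S 1.80 Å); unknown elements fall back to 1.70 Å.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Set, Tuple

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "ProteinStructure",
    "EpitopeAnnotation",
    "ResidueKey",
    "VDW_RADII",
    "DEFAULT_VDW_RADIUS",
    "read_pdb",
    "read_epitope_labels",
    "write_pdb",
]

#: residue key: (chain_id, seq_num, insertion_code); icode "" when absent.
ResidueKey = Tuple[str, int, str]

#: Van der Waals radii in Å for the elements that occur in protein heavy atoms.
#: Values match the NACCESS defaults so RSA stays comparable with its output.
VDW_RADII: Mapping[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
    "D": 1.20,
}

DEFAULT_VDW_RADIUS = 1.70

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# Common modified residues mapped to their parent standard residue.
_NONSTANDARD_PARENT = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "HYP": "PRO",
    "SEP": "SER", "TPO": "THR", "PTR": "TYR", "CSO": "CYS",
    "MLY": "LYS", "M3L": "LYS",
}

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class EmptySelectionError(ValueError):
    """No ATOM records survived chain selection / filtering."""


class LabelFileError(ValueError):
    """Malformed epitope label file."""


@dataclasses.dataclass
class Atom:
    """A heavy atom with coordinates and a fixed van der Waals radius."""

    serial: int
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Å
    vdw_radius: float
    residue_key: ResidueKey
    is_hydrogen: bool = False
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinates for atom {self.serial} {self.name}")
        if self.vdw_radius <= 0:
            raise ValueError(f"non-positive vdW radius for atom {self.serial} {self.name}")


@dataclasses.dataclass
class Residue:
    chain_id: str
    seq_num: int
    icode: str
    aa3: str
    aa1: str
    atoms: List[Atom] = dataclasses.field(default_factory=list)
    is_het: bool = False

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_num, self.icode)

    def atom(self, name: str) -> Optional[Atom]:
        """First atom with the given name, or None."""
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)


class ProteinStructure:
    """Ordered residues grouped by chain; the substrate for every feature.

    Residue keys ``(chain_id, seq_num, icode)`` are unique across the
    structure and every atom back-references its parent residue.
    """

    def __init__(self, pdb_id: str, residues: Sequence[Residue]):
        self.pdb_id = pdb_id
        self.residues: List[Residue] = list(residues)
        self._index: Dict[ResidueKey, Residue] = {}
        for res in self.residues:
            if not res.atoms:
                raise ValueError(f"residue {res.key} has no atoms")
            if res.key in self._index:
                raise ValueError(f"duplicate residue key {res.key}")
            self._index[res.key] = res

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __getitem__(self, key: ResidueKey) -> Residue:
        return self._index[key]

    def __contains__(self, key: ResidueKey) -> bool:
        return key in self._index

    @property
    def chain_ids(self) -> List[str]:
        seen: List[str] = []
        for res in self.residues:
            if res.chain_id not in seen:
                seen.append(res.chain_id)
        return seen

    @property
    def residue_count(self) -> int:
        return len(self.residues)

    @property
    def atom_count(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def atoms(self) -> Iterator[Atom]:
        for res in self.residues:
            yield from res.atoms

    def atom_coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in file order."""
        return np.array([a.coord for a in self.atoms()], dtype=float)

    def atom_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms()], dtype=float)

    def chain(self, chain_id: str) -> List[Residue]:
        return [r for r in self.residues if r.chain_id == chain_id]


def _aa_codes(resname: str) -> Tuple[str, str]:
    name = resname.strip().upper()
    name = _NONSTANDARD_PARENT.get(name, name)
    return name, _THREE_TO_ONE.get(name, "X")


def _pick_altloc(atoms: List[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties go to the first atom in file order
    best = atoms[0]
    for a in atoms[1:]:
        if a.occ > best.occ:
            best = a
    return best


def read_pdb(
    path: str | Path,
    chain_ids: Optional[Set[str]] = None,
    keep_het: bool = False,
) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    Parameters
    ----------
    path:
        PDB-format file.
    chain_ids:
        Chains to keep; ``None`` keeps all.
    keep_het:
        Keep non-water HETATM residues.  Waters are always discarded.

    Raises
    ------
    OSError
        Unreadable file.
    EmptySelectionError
        No atoms survive the chain selection and filtering.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    if len(st) == 0:
        raise EmptySelectionError(f"{path}: no coordinate model")
    model = st[0]

    residues: List[Residue] = []
    for chain in model:
        if chain_ids is not None and chain.name not in chain_ids:
            continue
        for gres in chain:
            if gres.name.strip().upper() in _WATER_NAMES or gres.is_water():
                continue
            is_het = gres.het_flag == "H"
            standard_parent = gres.name.strip().upper() in _NONSTANDARD_PARENT
            if is_het and not keep_het and not standard_parent:
                continue
            aa3, aa1 = _aa_codes(gres.name)
            icode = gres.seqid.icode.strip()
            res = Residue(
                chain_id=chain.name,
                seq_num=gres.seqid.num,
                icode=icode,
                aa3=aa3,
                aa1=aa1,
                is_het=is_het and not standard_parent,
            )
            by_name: Dict[str, List[gemmi.Atom]] = {}
            for ga in gres:
                by_name.setdefault(ga.name, []).append(ga)
            for name, variants in by_name.items():
                ga = _pick_altloc(variants)
                element = ga.element.name.upper()
                if element in ("H", "D"):
                    continue
                res.atoms.append(
                    Atom(
                        serial=ga.serial,
                        name=name,
                        element=element,
                        coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        vdw_radius=VDW_RADII.get(element, DEFAULT_VDW_RADIUS),
                        residue_key=res.key,
                        is_hydrogen=False,
                        altloc=ga.altloc if ga.altloc != "\x00" else "",
                        occupancy=ga.occ,
                    )
                )
            if res.atoms:
                residues.append(res)

    if not residues:
        sel = "all chains" if chain_ids is None else f"chains {sorted(chain_ids)}"
        raise EmptySelectionError(f"{path}: no ATOM records in {sel}")
    return ProteinStructure(pdb_id=st.name or path.stem, residues=residues)


class EpitopeAnnotation:
    """Binary epitope / non-epitope labels keyed by residue.

    Residues absent from the label map default to non-epitope, mirroring how
    benchmark annotations list only the epitope sites.
    """

    def __init__(self, labels: Optional[Mapping[ResidueKey, bool]] = None):
        self.labels: Dict[ResidueKey, bool] = dict(labels or {})

    def is_epitope(self, key: ResidueKey) -> bool:
        return self.labels.get(key, False)

    def epitope_keys(self) -> Set[ResidueKey]:
        return {k for k, v in self.labels.items() if v}

    def __len__(self) -> int:
        return len(self.labels)

    def validate_against(self, structure: ProteinStructure) -> None:
        """Raise if a labelled residue does not exist in the structure."""
        missing = [k for k in self.labels if k not in structure]
        if missing:
            raise LabelFileError(f"labelled residues absent from structure: {missing[:5]}")


_TRUE_LABELS = {"epitope", "e", "1", "true", "yes"}
_FALSE_LABELS = {"non_epitope", "nonepitope", "n", "0", "false", "no"}


def _parse_resnum(token: str) -> Tuple[int, str]:
    """Split '206' or '206A' into (206, 'A')."""
    token = token.strip()
    icode = ""
    if token and token[-1].isalpha():
        icode = token[-1].upper()
        token = token[:-1]
    return int(token), icode


def read_epitope_labels(path: str | Path) -> EpitopeAnnotation:
    """Read a whitespace/TSV label file: ``chain residue_number[icode] label``.

    Blank lines and ``#`` comments are ignored.  Duplicate entries with
    conflicting labels raise :class:`LabelFileError`.
    """
    labels: Dict[ResidueKey, bool] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise LabelFileError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            chain, numtok, labtok = parts
            try:
                seq_num, icode = _parse_resnum(numtok)
            except ValueError:
                raise LabelFileError(f"{path}:{lineno}: bad residue number {numtok!r}") from None
            lab = labtok.lower()
            if lab in _TRUE_LABELS:
                value = True
            elif lab in _FALSE_LABELS:
                value = False
            else:
                raise LabelFileError(f"{path}:{lineno}: unknown label {labtok!r}")
            key = (chain, seq_num, icode)
            if key in labels and labels[key] != value:
                raise LabelFileError(f"{path}:{lineno}: conflicting label for {key}")
            labels[key] = value
    return EpitopeAnnotation(labels)


def write_pdb(
    structure: ProteinStructure,
    path: str | Path,
    bfactors: Optional[Mapping[ResidueKey, float]] = None,
) -> None:
    """Write ATOM records; optional per-residue values go in the B-factor
    column (used to export hull levels for colouring)."""
    lines: List[str] = []
    serial = 0
    for res in structure:
        bfac = float(bfactors.get(res.key, 0.0)) if bfactors else 0.0
        for atom in res.atoms:
            serial += 1
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            lines.append(
                f"ATOM  {serial:>5d} {name:<4.4s}{atom.altloc or ' ':1s}{res.aa3:>3s} "
                f"{res.chain_id:1s}{res.seq_num:>4d}{res.icode or ' ':1s}   "
                f"{atom.coord[0]:8.3f}{atom.coord[1]:8.3f}{atom.coord[2]:8.3f}"
                f"{atom.occupancy:6.2f}{bfac:6.2f}          {atom.element:>2s}"
            )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
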
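import numpy as np
import pytest

from hullprot.fixtures import (
    extended_peptide_spec,
    make_globule,
    make_mini_pdb,
    make_shell_cloud,
)
from hullprot.structure_model import read_pdb


@pytest.fixture(scope="session")
def tripeptide_pdb(tmp_path_factory):
    """Isolated extended Gly-Ala-Gly mini-PDB on disk."""
    path = tmp_path_factory.mktemp("pdb") / "gag.pdb"
    path.write_text(make_mini_pdb(extended_peptide_spec(["GLY", "ALA", "GLY"])))
    return path


@pytest.fixture(scope="session")
def tripeptide(tripeptide_pdb):
    return read_pdb(tripeptide_pdb)


@pytest.fixture(scope="session")
def shell_cloud():
    """Three concentric shells with known peel levels and labels."""
    return make_shell_cloud(
        n_shells=3,
        pts_per_shell=200,
        radii=(30.0, 20.0, 10.0),
        epitope_fraction_by_shell=(0.5, 0.2, 0.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def globule():
    """Compact pseudo-antigen with surface-biased epitope labels."""
    return make_globule(n_residues=120, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20150805)
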
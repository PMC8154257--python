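import numpy as np
import pytest

import edcomplement as e


@pytest.fixture(scope="session")
def toy_pair():
    """Two single-1s hydrogen-like atoms 3 Å apart (exact analytic fit)."""
    return e.make_single_zeta_pair(zeta=1.0, Z=1, separation=3.0)


@pytest.fixture(scope="session")
def toy_points(toy_pair):
    grid = e.make_grid(toy_pair.ligand, spacing=0.1, margin=3.0)
    return e.overlap_points(toy_pair.model, toy_pair.receptor, toy_pair.ligand, grid)


@pytest.fixture(scope="session")
def toy_fit(toy_points):
    return e.fit_complementarity(toy_points)


@pytest.fixture(scope="session")
def displacement_run():
    """Fits for the displacement ensemble (references + displaced poses)."""
    receptor, references, displaced, model = e.make_displacement_ensemble()

    def fit(pose):
        grid = e.make_grid(pose, spacing=0.1, margin=3.0)
        pts = e.overlap_points(model, receptor, pose, grid)
        return e.fit_complementarity(pts, label=pose.label)

    ref_fits = [fit(p) for p in references]
    disp_fits = [fit(p) for p in displaced]
    return ref_fits, disp_fits


@pytest.fixture(scope="session")
def default_model():
    return e.DensityModel()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


# --- small PDB texts used by structio tests ---------------------------------

MULTI_MODEL_PDB = """\
MODEL        1
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1      12.104   7.134  -5.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      12.639   7.071  -4.147  1.00  0.00           C
ENDMDL
END
"""

# element columns intentionally blank: names must resolve C, N, O
BLANK_ELEMENT_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00
END
"""

COMPLEX_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       2.000  -0.800  -1.200  1.00  0.00           C
ATOM      6  N   GLY A   2       3.300   1.540   0.200  1.00  0.00           N
ATOM      7  CA  GLY A   2       3.970   2.840   0.200  1.00  0.00           C
HETATM    8  C1  LIG A   3       5.000   5.000   5.000  1.00  0.00           C
HETATM    9  O1  LIG A   3       6.200   5.100   5.000  1.00  0.00           O
HETATM   10  N1  LIG A   3       4.400   6.200   5.100  1.00  0.00           N
HETATM   11  C1  LIG B   4       8.000   8.000   8.000  1.00  0.00           C
HETATM   12  O   HOH A   5       9.000   1.000   1.000  1.00  0.00           O
HETATM   13  O   HOH A   6       9.500   1.500   1.500  1.00  0.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AALA A   1       1.458   0.000   0.000  0.60  0.00           C
ATOM      3  CA BALA A   1       1.558   0.100   0.000  0.40  0.00           C
END
"""


@pytest.fixture()
def pdb_file_factory(tmp_path):
    def write(text, name="test.pdb"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return write
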
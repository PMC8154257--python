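import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import edcomplement as e
from edcomplement.complement import POINT_COLUMNS
from edcomplement.density import BOHR_IN_ANGSTROM


def make_points_df(x, y):
    """Minimal overlap-point table with given sumdle/regressand columns."""
    m = len(x)
    df = pd.DataFrame({c: np.zeros(m) for c in POINT_COLUMNS})
    df["sumdle"] = np.asarray(x, dtype=float)
    df["y_value"] = np.asarray(y, dtype=float)
    return df


@pytest.mark.parametrize(
    "coords,margin,spacing,expected",
    [
        ([(0, 0, 0)], 0.5, 0.1, (11, 11, 11)),
        ([(0, 0, 0)], 0.0, 0.1, (1, 1, 1)),
        ([(0, 0, 0), (1, 2, 3)], 1.0, 0.5, (7, 9, 11)),
    ],
)
def test_make_grid_shapes(coords, margin, spacing, expected):
    atoms = [
        e.AtomRecord(i + 1, "C", 6, np.array(c, dtype=float))
        for i, c in enumerate(coords)
    ]
    grid = e.make_grid(e.MoleculePose(atoms, "g"), spacing=spacing, margin=margin)
    assert grid.shape == expected
    # grid point enumeration: count points per axis by brute force
    for axis in range(3):
        lo = min(c[axis] for c in coords) - margin
        hi = max(c[axis] for c in coords) + margin
        n = 0
        x = lo
        while x <= hi + 1e-9:
            n += 1
            x += spacing
        assert grid.shape[axis] == n


def test_disjoint_clouds_raise(toy_pair):
    far_ligand = toy_pair.ligand.translated((60.0, 0.0, 0.0), label="far")
    grid = e.make_grid(far_ligand, spacing=0.2, margin=2.0)
    with pytest.raises(e.NoOverlapError):
        e.overlap_points(toy_pair.model, toy_pair.receptor, far_ligand, grid)


def test_overlap_point_geometry_and_identity(toy_pair, toy_points):
    """Single-exponential algebra: y = ln(ZL*ZE) - 2*zeta*SUMDLE exactly,
    and the sigma decomposition identity holds at every point."""
    pts = toy_points
    # midline points: equidistant from both atoms
    sep = 3.0
    mid = pts[np.isclose(pts["x"], sep / 2)]
    assert len(mid) > 0
    assert np.allclose(mid["dist_ligand"], mid["dist_enzyme"], atol=1e-9)
    # exact line everywhere (zeta = 1 bohr^-1, Z = 1 -> intercept 0)
    expected_y = -2.0 / BOHR_IN_ANGSTROM * pts["sumdle"]
    assert np.abs(pts["y_value"] - expected_y).max() < 1e-9
    # Eq consistency: y = sigma_ligand + sigma_enzyme
    resid = pts["y_value"] - (pts["sigma_ligand"] + pts["sigma_enzyme"])
    assert np.abs(resid).max() < 1e-10
    # sumdle is the sum of the two top-contributor distances
    assert np.abs(pts["sumdle"] - pts["dist_ligand"] - pts["dist_enzyme"]).max() < 1e-12


def test_fit_exact_line_recovery():
    x = np.linspace(1.0, 8.0, 50)
    y = 6.52 - 4.03 * x
    fit = e.fit_complementarity(make_points_df(x, y))
    assert fit.a == pytest.approx(-4.03, abs=1e-12)
    assert fit.b == pytest.approx(6.52, abs=1e-12)
    assert fit.r2 == pytest.approx(1.0, abs=1e-12)


def test_fit_matches_normal_equations_and_linregress(rng):
    x = rng.uniform(1, 8, size=20)
    y = 6.0 - 4.0 * x + rng.normal(scale=0.5, size=20)
    fit = e.fit_complementarity(make_points_df(x, y))
    # closed-form normal equations, assembled independently
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    assert fit.b == pytest.approx(beta[0], abs=1e-10)
    assert fit.a == pytest.approx(beta[1], abs=1e-10)
    # scipy cross-check, including R^2
    lr = stats.linregress(x, y)
    assert fit.a == pytest.approx(lr.slope, abs=1e-10)
    assert fit.r2 == pytest.approx(lr.rvalue**2, abs=1e-10)
    n = len(x)
    assert fit.adj_r2 == pytest.approx(
        1 - (1 - fit.r2) * (n - 1) / (n - 2), abs=1e-12
    )


def test_fit_degenerate_errors():
    with pytest.raises(e.SingularFitError):
        e.fit_complementarity(make_points_df([1.0, 2.0], [0.0, 1.0]))
    with pytest.raises(e.SingularFitError):
        e.fit_complementarity(make_points_df([2.0, 2.0, 2.0], [0.0, 1.0, 2.0]))


def test_end_to_end_toy_fit(toy_pair, toy_fit):
    assert toy_fit.a == pytest.approx(toy_pair.expected_a, abs=1e-6)
    assert toy_fit.b == pytest.approx(toy_pair.expected_b, abs=1e-6)
    assert toy_fit.r2 > 1 - 1e-9
    assert toy_fit.residual_sd < 1e-8


def test_single_zeta_multi_atom_exactness():
    """With one common exponent the fit stays exact for any geometry in
    which atom tails do not mix (separations beyond the cutoff)."""
    zeta = 1.0
    model = e.single_zeta_model(zeta, [1], rho_min=0.005)
    mk = lambda s, el, c: e.AtomRecord(s, el, 1, np.array(c, dtype=float))
    receptor = e.MoleculePose(
        [mk(1, "H", (0.0, 0.0, 0.0)), mk(2, "H", (0.0, 0.0, 13.0))], "rec2"
    )
    ligand = e.MoleculePose(
        [mk(3, "H", (3.0, 0.0, 0.0)), mk(4, "H", (3.0, 0.0, 13.0))], "lig2"
    )
    grid = e.make_grid(ligand, spacing=0.2, margin=2.5)
    pts = e.overlap_points(model, receptor, ligand, grid)
    fit = e.fit_complementarity(pts)
    assert fit.residual_sd < 1e-8
    assert fit.a == pytest.approx(-2 * zeta / BOHR_IN_ANGSTROM, abs=1e-9)
    assert fit.b == pytest.approx(0.0, abs=1e-9)


def test_rigid_body_invariance_of_fit(toy_pair, toy_fit):
    """Rotating the whole complex changes the fit only by grid discretization."""
    angle = 0.41
    rot = np.array(
        [
            [math.cos(angle), -math.sin(angle), 0.0],
            [math.sin(angle), math.cos(angle), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    shift = np.array([0.37, -1.21, 0.55])

    def transform(pose, label):
        atoms = [
            e.AtomRecord(a.serial, a.element, a.atomic_number, rot @ a.coords + shift)
            for a in pose.atoms
        ]
        return e.MoleculePose(atoms, label=label)

    receptor = transform(toy_pair.receptor, "rec_t")
    ligand = transform(toy_pair.ligand, "lig_t")
    grid = e.make_grid(ligand, spacing=0.1, margin=3.0)
    fit = e.fit_complementarity(
        e.overlap_points(toy_pair.model, receptor, ligand, grid)
    )
    assert abs(fit.a - toy_fit.a) < 0.01
    assert abs(fit.b - toy_fit.b) < 0.05


def test_protruding_atom_leaves_fit_unchanged(toy_pair, toy_fit):
    """An extra ligand atom far outside the contact region (beyond the
    density cutoff) must not move the regression at all."""
    extra = e.AtomRecord(99, "H", 1, np.array([28.0, 0.0, 0.0]))
    ligand = e.MoleculePose(toy_pair.ligand.atoms + [extra], label="protruding")
    grid = e.make_grid(ligand, spacing=0.1, margin=3.0)
    fit = e.fit_complementarity(
        e.overlap_points(toy_pair.model, toy_pair.receptor, ligand, grid)
    )
    assert abs(fit.a - toy_fit.a) < 1e-6
    assert abs(fit.b - toy_fit.b) < 1e-6
    assert fit.n_points == toy_fit.n_points


def test_rho_min_monotone_tail(toy_pair):
    grid = e.make_grid(toy_pair.ligand, spacing=0.1, margin=3.0)
    strict = e.DensityModel(
        shells_by_element=toy_pair.model.shells_by_element, rho_min=0.003
    )
    loose = e.DensityModel(
        shells_by_element=toy_pair.model.shells_by_element, rho_min=0.001
    )
    pts_strict = e.overlap_points(strict, toy_pair.receptor, toy_pair.ligand, grid)
    pts_loose = e.overlap_points(loose, toy_pair.receptor, toy_pair.ligand, grid)
    assert len(pts_loose) > len(pts_strict)
    key = ["ix", "iy", "iz"]
    strict_set = set(map(tuple, pts_strict[key].to_numpy()))
    loose_set = set(map(tuple, pts_loose[key].to_numpy()))
    assert strict_set <= loose_set
    new = pts_loose[
        [tuple(t) not in strict_set for t in pts_loose[key].to_numpy()]
    ]
    assert new["sumdle"].min() >= pts_strict["sumdle"].min()


def test_points_tsv_export_deterministic(tmp_path, toy_points):
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    from edcomplement.complement import write_points_tsv

    write_points_tsv(toy_points, p1)
    write_points_tsv(toy_points.copy(), p2)
    assert p1.read_bytes() == p2.read_bytes()
    header = p1.read_text().splitlines()[0].split("\t")
    assert header == POINT_COLUMNS
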
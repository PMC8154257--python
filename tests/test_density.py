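import math

import numpy as np
import pytest
from scipy.integrate import quad

import edcomplement as e
from edcomplement.density import BOHR_IN_ANGSTROM, EBOHR3_TO_EANG3


def hydrogenic_model(zeta=1.0):
    return e.DensityModel(
        shells_by_element={"H": [e.SlaterShell(1, zeta, 1.0)]}
    )


def test_hydrogenic_center_density_closed_form():
    """A 1s shell with exponent zeta has rho(0) = zeta^3 / pi (atomic units)."""
    for zeta in (0.8, 1.0, 1.7):
        model = hydrogenic_model(zeta)
        expected = zeta**3 / math.pi * EBOHR3_TO_EANG3
        assert e.atomic_density(model, "H", 0.0) == pytest.approx(expected, rel=1e-12)


def test_far_field_decay(default_model):
    for el in ("H", "C", "S"):
        assert e.atomic_density(default_model, el, 50.0) < 1e-12


@pytest.mark.parametrize("element,z", [("C", 6), ("N", 7), ("O", 8)])
def test_radial_quadrature_equals_atomic_number(default_model, element, z):
    val = quad(
        lambda r: 4 * math.pi * r**2 * e.atomic_density(default_model, element, r),
        0.0, 50.0, limit=200,
    )[0]
    assert val == pytest.approx(z, rel=1e-3)


def test_unknown_element_raises(default_model):
    with pytest.raises(e.UnsupportedElementError):
        e.atomic_density(default_model, "Xq", 1.0)


def test_occupancy_sum_validated():
    with pytest.raises(ValueError):
        e.DensityModel(shells_by_element={"C": [e.SlaterShell(1, 1.0, 5.0)]})


def test_molecular_density_single_atom(toy_pair):
    pose = toy_pair.ligand
    pd = e.molecular_density(toy_pair.model, pose, pose.atoms[0].coords)
    assert pd.top_distance == 0.0
    assert pd.rho_total == pytest.approx(
        e.atomic_density(toy_pair.model, pose.atoms[0].element, 0.0)
    )


def test_molecular_density_symmetry_and_tiebreak():
    model = hydrogenic_model()
    atoms = [
        e.AtomRecord(1, "H", 1, np.array([0.0, 0.0, 0.0])),
        e.AtomRecord(2, "H", 1, np.array([2.0, 0.0, 0.0])),
    ]
    pose = e.MoleculePose(atoms, label="pair")
    pd = e.molecular_density(model, pose, (1.0, 0.0, 0.0))
    single = e.atomic_density(model, "H", 1.0)
    assert pd.rho_total == pytest.approx(2 * single, rel=1e-12)
    assert pd.top_atom.serial == 1  # tie broken to lower serial


def test_molecular_density_bruteforce_oracle(rng):
    """Total density equals a cutoff-free brute-force sum over atoms."""
    model = e.DensityModel()
    coords = rng.uniform(-2, 2, size=(3, 3))
    elements = ["C", "N", "O"]
    atoms = [
        e.AtomRecord(i + 1, el, {"C": 6, "N": 7, "O": 8}[el], coords[i])
        for i, el in enumerate(elements)
    ]
    pose = e.MoleculePose(atoms, label="toy3")
    probe = np.array([0.3, -0.4, 0.8])
    brute = sum(
        e.atomic_density(model, a.element, float(np.linalg.norm(probe - a.coords)))
        for a in atoms
    )
    pd = e.molecular_density(model, pose, probe)
    assert pd.rho_total == pytest.approx(brute, abs=1e-9)


def test_center_density_isolated_and_pair():
    model = hydrogenic_model()
    a1 = e.AtomRecord(1, "H", 1, np.array([0.0, 0.0, 0.0]))
    solo = e.MoleculePose([a1], label="solo")
    assert e.center_density(model, solo, a1) == pytest.approx(
        e.atomic_density(model, "H", 0.0)
    )
    a2 = e.AtomRecord(2, "H", 1, np.array([1.0, 0.0, 0.0]))
    pair = e.MoleculePose([a1, a2], label="pair")
    expected = e.atomic_density(model, "H", 0.0) + e.atomic_density(model, "H", 1.0)
    assert e.center_density(model, pair, a1) == pytest.approx(expected, rel=1e-12)
    # neighbor tails only ever add density
    assert e.center_density(model, pair, a1) >= e.atomic_density(model, "H", 0.0)
    # isolated mode ignores the neighbor
    iso = e.DensityModel(
        shells_by_element={"H": [e.SlaterShell(1, 1.0, 1.0)]},
        center_mode="isolated",
    )
    assert e.center_density(iso, pair, a1) == pytest.approx(
        e.atomic_density(iso, "H", 0.0)
    )


def test_center_density_membership_error(toy_pair):
    stray = e.AtomRecord(99, "H", 1, np.array([9.0, 9.0, 9.0]))
    with pytest.raises(e.MembershipError):
        e.center_density(toy_pair.model, toy_pair.ligand, stray)


def test_positivity_and_radial_monotonic_decay(default_model):
    r = np.linspace(0.0, 12.0, 2000)
    for el in default_model.shells_by_element:
        rho = e.atomic_density(default_model, el, r)
        assert np.all(rho > 0)
        # monotone beyond the outermost density maximum
        peak = int(np.argmax(rho))
        tail = rho[peak:]
        assert np.all(np.diff(tail) <= 1e-15)


def test_rigid_motion_equivariance(rng):
    model = e.DensityModel()
    coords = rng.uniform(-2, 2, size=(4, 3))
    atoms = [e.AtomRecord(i + 1, "C", 6, coords[i]) for i in range(4)]
    pose = e.MoleculePose(atoms, label="orig")
    probes = rng.uniform(-3, 3, size=(10, 3))
    # random rotation + translation
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = np.array([5.0, -2.0, 1.0])
    moved = e.MoleculePose(
        [e.AtomRecord(i + 1, "C", 6, q @ coords[i] + t) for i in range(4)],
        label="moved",
    )
    from edcomplement.density import evaluate_density

    rho0, _, _, d0 = evaluate_density(model, pose, probes)
    rho1, _, _, d1 = evaluate_density(model, moved, probes @ q.T + t)
    assert np.abs(rho0 - rho1).max() < 1e-10
    assert np.abs(d0 - d1).max() < 1e-9


def test_parameter_file_round_trip(tmp_path, default_model):
    path = tmp_path / "params.txt"
    lines = ["# round trip"]
    for el, shells in default_model.shells_by_element.items():
        for s in shells:
            lines.append(f"{el} {s.principal_n} {s.zeta} {s.occupancy}")
    path.write_text("\n".join(lines) + "\n")
    loaded = e.load_parameters(path)
    assert set(loaded) == set(default_model.shells_by_element)
    for el in loaded:
        assert loaded[el] == default_model.shells_by_element[el]


def test_hydrogen_exclusion_flag():
    model = e.DensityModel(include_hydrogens=False)
    atoms = [
        e.AtomRecord(1, "C", 6, np.array([0.0, 0.0, 0.0])),
        e.AtomRecord(2, "H", 1, np.array([1.1, 0.0, 0.0])),
    ]
    pose = e.MoleculePose(atoms, label="ch")
    pd = e.molecular_density(model, pose, (1.1, 0.0, 0.0))
    assert pd.rho_total == pytest.approx(
        e.atomic_density(model, "C", 1.1), rel=1e-12
    )
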
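"""Synthetic toy complexes with analytically known ground truth.

For atoms carrying a single 1s Slater shell with a common exponent zeta,
the log-density of each molecule is exactly linear in the distance to its
(only relevant) atom, so the complementarity regression is exact with

    slope  a = -2 * zeta   (converted from bohr^-1 to Å^-1)
    intercept b = ln(Z_ligand * Z_enzyme)
    R^2 = 1

independent of geometry. These pairs are the closed-form oracle for the
end-to-end pipeline. Displacement sensitivity, by contrast, requires
multi-shell atoms (steep core decay near contact, shallow valence decay
further out), which the displacement ensemble uses.

All randomness flows through one explicitly passed seeded generator; no
global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

from .complement import POINT_COLUMNS
from .density import BOHR_IN_ANGSTROM, DensityModel, SlaterShell
from .structio import AtomRecord, MoleculePose


def _atom(serial, element, z, coords, name=None, resname="LIG", chain="A",
          resseq=1, hetero=True):
    return AtomRecord(
        serial=serial, element=element, atomic_number=z,
        coords=np.asarray(coords, dtype=float),
        name=name or f"{element}{serial}", resname=resname, chain=chain,
        resseq=resseq, is_hetero=hetero,
    )


def single_zeta_model(zeta: float, atomic_numbers: list[int],
                      rho_min: float = 0.001) -> DensityModel:
    """Density model giving each listed element one 1s shell with a common
    exponent and occupancy equal to its atomic number."""
    shells = {
        gemmi.Element(z).name: [SlaterShell(1, zeta, float(z))]
        for z in set(atomic_numbers)
    }
    return DensityModel(shells_by_element=shells, rho_min=rho_min)


@dataclass(frozen=True)
class ToyPair:
    """A two-atom toy complex with its exact expected fit."""

    receptor: MoleculePose
    ligand: MoleculePose
    model: DensityModel
    expected_a: float  # Å^-1
    expected_b: float
    expected_r2: float = 1.0


def make_single_zeta_pair(
    zeta: float = 1.0, Z: int = 1, separation: float = 3.0
) -> ToyPair:
    """One receptor atom at the origin, one ligand atom ``separation`` Å
    along x, both single-1s with exponent ``zeta`` (bohr^-1)."""
    if zeta <= 0:
        raise ValueError("zeta must be positive")
    if not 1.0 <= separation <= 8.0:
        raise ValueError("separation must lie in [1, 8] Å")
    el = gemmi.Element(Z).name
    receptor = MoleculePose(
        [_atom(1, el, Z, (0.0, 0.0, 0.0), resname="REC", hetero=False)],
        label="toy_receptor",
    )
    ligand = MoleculePose(
        [_atom(2, el, Z, (separation, 0.0, 0.0))], label="toy_ligand"
    )
    model = single_zeta_model(zeta, [Z])
    return ToyPair(
        receptor=receptor,
        ligand=ligand,
        model=model,
        expected_a=-2.0 * zeta / BOHR_IN_ANGSTROM,
        expected_b=2.0 * math.log(Z),
    )


@dataclass
class ToySpec:
    """Specification of a synthetic pose ensemble."""

    n_ligand_atoms: int = 5
    elements: tuple[str, ...] = ("C", "C", "N", "O", "C")
    separation: float = 3.0
    jitter_sd: float = 0.1
    seed: int = 0


def make_pose_ensemble(spec: ToySpec) -> tuple[list[MoleculePose], dict]:
    """A reference pose plus displaced/permuted/jittered copies.

    Returns (poses, manifest) where the manifest records ground-truth
    RMSD values (naive and Hungarian) for the copies that have exact
    ones. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    elements = list(spec.elements)
    while len(elements) < spec.n_ligand_atoms:
        elements.append("C")
    elements = elements[: spec.n_ligand_atoms]
    coords = rng.normal(scale=1.5, size=(spec.n_ligand_atoms, 3))
    atoms = [
        _atom(i + 1, el, gemmi.Element(el).atomic_number, coords[i])
        for i, el in enumerate(elements)
    ]
    ref = MoleculePose(atoms, label="ref")

    poses = [ref]
    manifest: dict[str, dict] = {"ref": {"rmsd_naive": 0.0, "rmsd_hungarian": 0.0}}

    shifted2 = ref.translated((0.0, 0.0, 2.0), label="shift_2A")
    poses.append(shifted2)
    manifest["shift_2A"] = {"rmsd_naive": 2.0, "rmsd_hungarian": 2.0}

    shifted5 = ref.translated((3.0, 4.0, 0.0), label="shift_5A")
    poses.append(shifted5)
    manifest["shift_5A"] = {"rmsd_naive": 5.0, "rmsd_hungarian": 5.0}

    # permute atoms within one element class: Hungarian RMSD must vanish
    perm_atoms = list(ref.atoms)
    carbon_idx = [i for i, a in enumerate(perm_atoms) if a.element == "C"]
    if len(carbon_idx) >= 2:
        i, j = carbon_idx[0], carbon_idx[1]
        a_i, a_j = perm_atoms[i], perm_atoms[j]
        swapped_i = _atom(a_i.serial, a_i.element, a_i.atomic_number, a_j.coords,
                          name=a_i.name)
        swapped_j = _atom(a_j.serial, a_j.element, a_j.atomic_number, a_i.coords,
                          name=a_j.name)
        perm_atoms[i], perm_atoms[j] = swapped_i, swapped_j
    poses.append(MoleculePose(perm_atoms, label="perm"))
    manifest["perm"] = {"rmsd_hungarian": 0.0}

    jitter = rng.normal(scale=spec.jitter_sd, size=(spec.n_ligand_atoms, 3))
    jit_atoms = [
        _atom(a.serial, a.element, a.atomic_number, a.coords + jitter[k],
              name=a.name)
        for k, a in enumerate(ref.atoms)
    ]
    poses.append(MoleculePose(jit_atoms, label="jitter"))
    manifest["jitter"] = {
        "rmsd_naive": float(np.sqrt((jitter**2).sum(axis=1).mean()))
    }
    return poses, manifest


def make_rotated_substituent_pair() -> tuple[MoleculePose, MoleculePose, frozenset[int]]:
    """Two poses of an 8-atom ligand differing only by a 180°-rotated
    terminal group, mimicking a substituent protruding out of the pocket.

    Returns (pose_a, pose_b, substituent_serials). The core atoms are
    identical, so excluding the substituent drives the RMSD to zero while
    the naive all-atom RMSD stays well above 1 Å.
    """
    core = [
        (1, "C", (0.0, 0.0, 0.0)),
        (2, "C", (1.4, 0.0, 0.0)),
        (3, "N", (2.1, 1.2, 0.0)),
        (4, "O", (-0.7, 1.2, 0.0)),
        (5, "C", (2.1, -1.2, 0.0)),
    ]
    attach = np.array([3.5, -1.2, 0.0])
    sub = [
        (6, "C", attach + (0.0, 0.0, 0.0)),
        (7, "C", attach + (1.2, 0.9, 0.0)),
        (8, "O", attach + (1.2, -0.9, 0.5)),
    ]

    def build(sub_coords, label):
        atoms = [
            _atom(s, el, gemmi.Element(el).atomic_number, c)
            for (s, el, _), c in zip(
                core + sub, [np.asarray(c) for _, _, c in core] + sub_coords
            )
        ]
        return MoleculePose(atoms, label=label)

    sub_a = [np.asarray(c, dtype=float) for _, _, c in sub]
    # rotate the group 180° about the z axis through the attachment atom
    sub_b = [attach + np.array([-1, -1, 1]) * (c - attach) for c in sub_a]
    pose_a = build(sub_a, "sub_ref")
    pose_b = build(sub_b, "sub_rot")
    return pose_a, pose_b, frozenset({6, 7, 8})


def make_displacement_ensemble(
    displacements: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0),
    reference_offsets: tuple[float, ...] = (-0.05, 0.0, 0.05),
    jitter: float = 0.02,
    seed: int = 0,
) -> tuple[MoleculePose, list[MoleculePose], list[MoleculePose], DensityModel]:
    """A carbon receptor wall and a two-carbon ligand pulled away from it.

    Returns (receptor, reference_poses, displaced_poses, model). The
    displaced poses slide the ligand along +x (away from the wall) by
    each displacement; the reference poses straddle the optimum with
    small x offsets plus lateral jitter, so their envelope brackets the
    undisplaced slope but not the displaced ones.

    The model gives carbon two 1s shells (a steep core and a diffuse
    valence exponential). The log density is then convex in distance, so
    the fitted slope rises monotonically as the contact gap widens —
    the mechanism by which corrupted poses drift to higher slopes.
    Displacements are kept within ~1 Å so the electron clouds stay in
    contact; beyond that the overlap region collapses onto the inclusion
    threshold and the fit degenerates.
    """
    rng = np.random.default_rng(seed)
    rec_atoms = [
        _atom(i + 1, "C", 6, (0.0, y, z), resname="REC", hetero=False)
        for i, (y, z) in enumerate([(0.0, 0.0), (1.4, 0.0), (0.7, 1.2)])
    ]
    receptor = MoleculePose(rec_atoms, label="wall")
    base = np.array([[2.8, 0.35, 0.3], [2.8, 1.05, 0.7]])

    def ligand_at(offset: np.ndarray, label: str) -> MoleculePose:
        atoms = [
            _atom(10 + i, "C", 6, base[i] + offset) for i in range(base.shape[0])
        ]
        return MoleculePose(atoms, label=label)

    references = []
    for k, dx in enumerate(reference_offsets):
        off = np.array([dx, *rng.normal(scale=jitter, size=2)])
        references.append(ligand_at(off, f"ref_{k}"))
    displaced = [
        ligand_at(np.array([d, 0.0, 0.0]), f"disp_{d:g}") for d in displacements
    ]
    model = DensityModel(
        shells_by_element={
            "C": [SlaterShell(1, 2.2, 5.0), SlaterShell(1, 0.9, 1.0)]
        },
        rho_min=1e-4,
    )
    return receptor, references, displaced, model


def make_clustered_points(
    n_blobs: int = 3,
    gap: float = 0.5,
    spacing: float = 0.1,
    seed: int = 0,
    blob_size: int = 8,
) -> tuple[pd.DataFrame, int]:
    """Grid-aligned point blobs with a known connected-component count.

    Each blob is a contiguous random walk on the grid; blobs are placed
    along x so consecutive blobs are at least ``gap`` apart (gap must
    exceed the spacing). Returns an overlap-point-style table and the
    expected cluster count at threshold = spacing.
    """
    if gap <= spacing:
        raise ValueError("gap must exceed spacing")
    rng = np.random.default_rng(seed)
    steps = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
    )
    all_idx: list[np.ndarray] = []
    x_offset = 0
    for b in range(n_blobs):
        seen = {(0, 0, 0)}
        cur = np.zeros(3, dtype=int)
        while len(seen) < blob_size:
            cur = cur + steps[rng.integers(0, 6)]
            seen.add(tuple(cur))
        idx = np.array(sorted(seen), dtype=int)
        idx[:, 1:] -= idx[:, 1:].min(axis=0)  # keep y,z nonnegative
        idx[:, 0] += x_offset - idx[:, 0].min()
        all_idx.append(idx)
        width = idx[:, 0].max() - x_offset + 1
        x_offset += width + int(math.ceil(gap / spacing)) + 1
    idx = np.concatenate(all_idx)
    m = idx.shape[0]
    df = pd.DataFrame(
        {
            "x": idx[:, 0] * spacing,
            "y": idx[:, 1] * spacing,
            "z": idx[:, 2] * spacing,
            "ix": idx[:, 0], "iy": idx[:, 1], "iz": idx[:, 2],
            "rho_ligand": np.full(m, 0.01),
            "rho_enzyme": np.full(m, 0.01),
            "lig_serial": np.ones(m, dtype=int),
            "enz_serial": np.full(m, 2, dtype=int),
            "lig_name": ["C1"] * m,
            "enz_name": ["C2"] * m,
            "enz_resname": ["REC"] * m,
            "dist_ligand": np.full(m, 1.0),
            "dist_enzyme": np.full(m, 1.0),
            "sumdle": np.full(m, 2.0),
            "rho_n": np.zeros(m),
            "sigma_ligand": np.zeros(m),
            "sigma_enzyme": np.zeros(m),
            "y_value": np.zeros(m),
        }
    )[POINT_COLUMNS]
    return df, n_blobs
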
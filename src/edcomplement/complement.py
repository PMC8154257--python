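"""Complementarity analysis: overlap grid, per-point descriptors, and the
linear regression relating log density overlap to contact distance.

At every grid point m in the intermolecular region where both electron
clouds contribute, the method records

    SUMDLE_m = dist_ligand + dist_enzyme        (Å)
    rhoN_m   = ln( N_L * N_E / (rho_LC * rho_EC) )
    y_m      = ln( rho_ligand * rho_enzyme ) + rhoN_m
             = sigma_ligand + sigma_enzyme

with sigma_ligand = ln(rho_ligand * N_L / rho_LC) and analogously for the
enzyme side, where N_L/N_E are atomic numbers of the top-contributing
atoms and rho_LC/rho_EC the densities at those atoms' centers. Ordinary
least squares of y on SUMDLE yields the complementarity line
y = b + a * SUMDLE: slope a (Å^-1) tracks binding efficiency, intercept
b is dimensionless. Logarithm arguments are rendered dimensionless by
dividing by 1 e/Å^3, implicitly.

Overlap points are carried as a pandas DataFrame (one row per grid
point, ordered grid-index lexicographically) with columns::

    x y z ix iy iz rho_ligand rho_enzyme lig_serial enz_serial
    lig_name enz_name enz_resname dist_ligand dist_enzyme
    sumdle rho_n sigma_ligand sigma_enzyme y_value

("y_value" is the regressand; "y" is the Cartesian coordinate.)
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .density import DensityModel, center_density, evaluate_density
from .errors import EmptyPoseError, NoOverlapError, SingularFitError
from .structio import MoleculePose

POINT_COLUMNS = [
    "x", "y", "z", "ix", "iy", "iz",
    "rho_ligand", "rho_enzyme",
    "lig_serial", "enz_serial",
    "lig_name", "enz_name", "enz_resname",
    "dist_ligand", "dist_enzyme",
    "sumdle", "rho_n", "sigma_ligand", "sigma_enzyme", "y_value",
]


@dataclass(frozen=True)
class GridSpec:
    """A regular axis-aligned grid: point k = origin + k * spacing per axis."""

    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(s < 1 for s in self.shape):
            raise ValueError("shape must be positive")

    @property
    def n_points(self) -> int:
        return int(np.prod(self.shape))

    def indices(self) -> np.ndarray:
        """(M, 3) integer grid indices in lexicographic order."""
        grids = np.meshgrid(*(np.arange(s) for s in self.shape), indexing="ij")
        return np.stack(grids, axis=-1).reshape(-1, 3)

    def points(self) -> np.ndarray:
        """(M, 3) Cartesian coordinates (Å), grid-index lexicographic order."""
        return np.asarray(self.origin) + self.indices() * self.spacing


def make_grid(ligand: MoleculePose, spacing: float = 0.1, margin: float = 3.0) -> GridSpec:
    """Grid over the ligand bounding box expanded by ``margin`` per side.

    The default 0.1 Å spacing gives 1000 points per Å^3; the 3 Å margin
    comfortably covers the contact-distance range of interest (~8 Å total).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if margin < 0:
        raise ValueError("margin must be nonnegative")
    coords = ligand.coords
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    shape = tuple(int(math.floor((h - l) / spacing + 1e-9)) + 1 for l, h in zip(lo, hi))
    return GridSpec(origin=tuple(lo), spacing=spacing, shape=shape)


def overlap_points(
    model: DensityModel,
    receptor: MoleculePose,
    ligand: MoleculePose,
    grid: GridSpec,
) -> pd.DataFrame:
    """Per-point complementarity descriptors on the overlap region.

    Keeps grid points where both molecules contribute at least
    ``model.rho_min`` (e/Å^3). Raises :class:`NoOverlapError` when no
    point qualifies — the poses' electron clouds do not touch.
    """
    pts = grid.points()
    idx = grid.indices()

    lig_rho, lig_top, _, lig_dist = evaluate_density(model, ligand, pts)
    keep = lig_rho >= model.rho_min
    if not keep.any():
        raise NoOverlapError("ligand density nowhere exceeds rho_min on the grid")
    pts, idx = pts[keep], idx[keep]
    lig_rho, lig_top, lig_dist = lig_rho[keep], lig_top[keep], lig_dist[keep]

    enz_rho, enz_top, _, enz_dist = evaluate_density(model, receptor, pts)
    keep = enz_rho >= model.rho_min
    if not keep.any():
        raise NoOverlapError(
            "no grid point carries both ligand and receptor density above rho_min"
        )
    pts, idx = pts[keep], idx[keep]
    lig_rho, lig_top, lig_dist = lig_rho[keep], lig_top[keep], lig_dist[keep]
    enz_rho, enz_top, enz_dist = enz_rho[keep], enz_top[keep], enz_dist[keep]

    lig_atoms = model.active_atoms(ligand)
    enz_atoms = model.active_atoms(receptor)

    def center_table(pose: MoleculePose, atoms: list) -> np.ndarray:
        return np.array([center_density(model, pose, a) for a in atoms])

    lig_centers = center_table(ligand, lig_atoms)
    enz_centers = center_table(receptor, enz_atoms)

    n_l = np.array([a.atomic_number for a in lig_atoms], dtype=float)[lig_top]
    n_e = np.array([a.atomic_number for a in enz_atoms], dtype=float)[enz_top]
    rho_lc = lig_centers[lig_top]
    rho_ec = enz_centers[enz_top]

    sigma_ligand = np.log(lig_rho * n_l / rho_lc)
    sigma_enzyme = np.log(enz_rho * n_e / rho_ec)
    rho_n = np.log(n_l * n_e / (rho_lc * rho_ec))
    y = np.log(lig_rho * enz_rho) + rho_n

    df = pd.DataFrame(
        {
            "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2],
            "ix": idx[:, 0], "iy": idx[:, 1], "iz": idx[:, 2],
            "rho_ligand": lig_rho, "rho_enzyme": enz_rho,
            "lig_serial": [lig_atoms[i].serial for i in lig_top],
            "enz_serial": [enz_atoms[i].serial for i in enz_top],
            "lig_name": [lig_atoms[i].name for i in lig_top],
            "enz_name": [enz_atoms[i].name for i in enz_top],
            "enz_resname": [enz_atoms[i].resname for i in enz_top],
            "dist_ligand": lig_dist, "dist_enzyme": enz_dist,
            "sumdle": lig_dist + enz_dist,
            "rho_n": rho_n,
            "sigma_ligand": sigma_ligand, "sigma_enzyme": sigma_enzyme,
            "y_value": y,
        }
    )
    return df.reset_index(drop=True)


@dataclass(frozen=True)
class ComplementarityFit:
    """Result of the complementarity regression y = b + a * SUMDLE."""

    a: float
    b: float
    r2: float
    adj_r2: float
    n_points: int
    residual_sd: float
    label: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def fit_complementarity(points: pd.DataFrame, label: str = "") -> ComplementarityFit:
    """Ordinary least squares of the regressand y on SUMDLE."""
    x = np.asarray(points["sumdle"], dtype=float)
    y = np.asarray(points["y_value"], dtype=float)
    n = x.size
    if n < 3:
        raise SingularFitError(f"need >= 3 overlap points, got {n}")
    if np.ptp(x) == 0:
        raise SingularFitError("all SUMDLE values identical; regression is singular")
    xm, ym = x.mean(), y.mean()
    dx = x - xm
    slope = float(dx @ (y - ym) / (dx @ dx))
    intercept = float(ym - slope * xm)
    resid = y - (intercept + slope * x)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - ym) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    residual_sd = math.sqrt(ss_res / (n - 2))
    return ComplementarityFit(
        a=slope, b=intercept, r2=r2, adj_r2=adj_r2,
        n_points=n, residual_sd=residual_sd, label=label,
    )


def _fmt(v) -> str:
    if isinstance(v, (float, np.floating)):
        return f"{v:.6g}"
    return str(v)


def write_points_tsv(points: pd.DataFrame, path: str | Path) -> None:
    """Export the overlap-point table as TSV (floats to 6 significant digits)."""
    cols = list(points.columns)
    lines = ["\t".join(cols)]
    for row in points.itertuples(index=False):
        lines.append("\t".join(_fmt(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_fit_json(fit: ComplementarityFit, path: str | Path) -> None:
    d = fit.to_dict()
    out = {
        k: (round(v, 10) if isinstance(v, float) else v) for k, v in d.items()
    }
    Path(path).write_text(json.dumps(out, indent=2, sort_keys=True) + "\n")
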
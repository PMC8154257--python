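"""Pose ranking and envelope classification from complementarity fits.

Crystallographic and minimized poses of a given receptor occupy a narrow
band of (slope, intercept) values; docked poses scatter widely. The
reference envelope is the min-max box of the reference fits, and a docked
pose is complementarity-consistent when its slope falls inside the
reference slope interval (closed). Because slope and intercept are nearly
collinear across poses, classification uses the slope alone; the
intercept interval is reported for diagnostics. More negative slopes
correspond to higher binding efficiency, so poses are ranked ascending
by slope.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .complement import ComplementarityFit
from .errors import InsufficientReferencesError, SingularFitError


@dataclass(frozen=True)
class ReferenceEnvelope:
    """Min-max box (plus mean/sd) of reference-fit coefficients."""

    a_min: float
    a_max: float
    b_min: float
    b_max: float
    a_mean: float
    a_sd: float
    b_mean: float
    b_sd: float
    n_refs: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PoseScorecard:
    label: str
    fit: ComplementarityFit
    inside_envelope: bool | None = None
    rank: int | None = None
    rmsd_to_reference: float | None = None
    n_clusters: int | None = None

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "a": self.fit.a,
            "b": self.fit.b,
            "r2": self.fit.r2,
            "adj_r2": self.fit.adj_r2,
            "n_points": self.fit.n_points,
            "inside_envelope": self.inside_envelope,
            "rank": self.rank,
            "rmsd": self.rmsd_to_reference,
            "n_clusters": self.n_clusters,
        }
        return d


def reference_envelope(fits: list[ComplementarityFit]) -> ReferenceEnvelope:
    """Envelope spanned by the reference (crystallographic/minimized) fits."""
    if len(fits) < 2:
        raise InsufficientReferencesError(
            f"need >= 2 reference fits to build an envelope, got {len(fits)}"
        )
    a = np.array([f.a for f in fits], dtype=float)
    b = np.array([f.b for f in fits], dtype=float)
    return ReferenceEnvelope(
        a_min=float(a.min()), a_max=float(a.max()),
        b_min=float(b.min()), b_max=float(b.max()),
        a_mean=float(a.mean()), a_sd=float(a.std(ddof=1)),
        b_mean=float(b.mean()), b_sd=float(b.std(ddof=1)),
        n_refs=len(fits),
    )


def classify_pose(fit: ComplementarityFit, env: ReferenceEnvelope) -> bool:
    """True when the pose's slope lies inside the closed reference interval."""
    return env.a_min <= fit.a <= env.a_max


def rank_poses(scorecards: list[PoseScorecard]) -> list[PoseScorecard]:
    """Rank poses ascending by slope (most negative = best), ties by
    higher R², then label. Ranks are written onto the scorecards."""
    if not scorecards:
        raise ValueError("need at least one pose to rank")
    ordered = sorted(scorecards, key=lambda s: (s.fit.a, -s.fit.r2, s.label))
    for i, s in enumerate(ordered):
        s.rank = i + 1
    return ordered


def slope_intercept_line(fits: list[ComplementarityFit]) -> dict:
    """OLS of intercept b on slope a across complexes.

    Across poses of a receptor the two coefficients fall on one line
    (adjusted R² near 1), which is why the slope alone suffices for
    classification.
    """
    if len(fits) < 3:
        raise SingularFitError(f"need >= 3 fits, got {len(fits)}")
    a = np.array([f.a for f in fits], dtype=float)
    b = np.array([f.b for f in fits], dtype=float)
    if np.ptp(a) == 0:
        raise SingularFitError("all slopes identical; line fit is singular")
    am, bm = a.mean(), b.mean()
    da = a - am
    slope = float(da @ (b - bm) / (da @ da))
    intercept = float(bm - slope * am)
    resid = b - (intercept + slope * a)
    ss_res = float(resid @ resid)
    ss_tot = float(((b - bm) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    n = len(fits)
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return {"slope": slope, "intercept": intercept, "r2": r2, "adj_r2": adj_r2, "n": n}


def write_report_json(
    scorecards: list[PoseScorecard],
    env: ReferenceEnvelope | None,
    line: dict | None,
    path: str | Path,
) -> None:
    report = {
        "poses": [s.to_dict() for s in scorecards],
        "envelope": env.to_dict() if env is not None else None,
        "line": line,
    }
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def write_report_tsv(scorecards: list[PoseScorecard], path: str | Path) -> None:
    cols = ["label", "a", "b", "r2", "adj_r2", "n_points",
            "inside_envelope", "rank", "rmsd", "n_clusters"]
    lines = ["\t".join(cols)]
    for s in scorecards:
        d = s.to_dict()
        row = []
        for c in cols:
            v = d[c]
            if v is None:
                row.append("NA")
            elif isinstance(v, float):
                row.append(f"{v:.6g}")
            else:
                row.append(str(v))
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")
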
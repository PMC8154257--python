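"""Friends-of-friends clustering of overlap points into discrete contacts.

Two points are friends if their Cartesian distance is at most the linkage
threshold; clusters are the transitive closure of the friend relation
(single-linkage connected components). With the threshold equal to the
grid spacing this is exactly 6-neighborhood connected-component labelling
on the generation grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

#: absorbs floating-point error in grid-step distances
LINKAGE_EPS = 1e-9


@dataclass
class ContactCluster:
    """One connected set of overlap points and its summary statistics."""

    cluster_id: int
    points: pd.DataFrame
    n_points: int
    max_ln_rho_product: float
    min_sumdle: float
    dominant_pair: tuple[int, int]  # (ligand serial, enzyme serial)


def _component_labels(coords: np.ndarray, threshold: float) -> np.ndarray:
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=threshold + LINKAGE_EPS, output_type="ndarray")
    n = coords.shape[0]
    if pairs.size:
        data = np.ones(pairs.shape[0], dtype=bool)
        graph = sparse.coo_matrix(
            (data, (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
    else:
        graph = sparse.coo_matrix((n, n), dtype=bool)
    _, labels = connected_components(graph, directed=False)
    return labels


def cluster_contacts(
    points: pd.DataFrame,
    threshold: float = 0.1,
    *,
    connectivity: int = 6,
    strength_floor: float | None = None,
) -> list[ContactCluster]:
    """Partition overlap points into contact clusters.

    Parameters
    ----------
    points : overlap-point table (see :mod:`edcomplement.complement`).
    threshold : linkage distance, Å. Default 0.1 Å, the grid spacing, so
        diagonal grid neighbors (0.1*sqrt(2) Å apart) are NOT linked.
    connectivity : 6 links points within ``threshold``; 26 additionally
        links grid diagonals by extending the radius to threshold*sqrt(3).
    strength_floor : optional minimum ln(rho_ligand * rho_enzyme); points
        below it are dropped before clustering (None keeps everything).

    Returns clusters ordered by descending size, ties broken by the
    lexicographically smallest grid index among each cluster's points.
    Empty input yields an empty list.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if connectivity not in (6, 26):
        raise ValueError("connectivity must be 6 or 26")
    df = points
    if strength_floor is not None:
        keep = np.log(df["rho_ligand"] * df["rho_enzyme"]) >= strength_floor
        df = df[keep].reset_index(drop=True)
    if len(df) == 0:
        return []
    radius = threshold * (math.sqrt(3.0) if connectivity == 26 else 1.0)
    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    labels = _component_labels(coords, radius)

    clusters: list[ContactCluster] = []
    for lab in np.unique(labels):
        sub = df[labels == lab]
        clusters.append(_summarize(sub))
    order = sorted(
        range(len(clusters)),
        key=lambda i: (-clusters[i].n_points, _min_grid_index(clusters[i].points)),
    )
    out = []
    for rank, i in enumerate(order):
        c = clusters[i]
        c.cluster_id = rank
        c.points = c.points.assign(cluster_id=rank)
        out.append(c)
    return out


def _min_grid_index(sub: pd.DataFrame) -> tuple[int, int, int]:
    arr = sub[["ix", "iy", "iz"]].to_numpy(dtype=int)
    i = np.lexsort((arr[:, 2], arr[:, 1], arr[:, 0]))[0]
    return tuple(arr[i])


def _summarize(sub: pd.DataFrame) -> ContactCluster:
    ln_rho = np.log(sub["rho_ligand"].to_numpy() * sub["rho_enzyme"].to_numpy())
    pairs = list(zip(sub["lig_serial"], sub["enz_serial"]))
    counts: dict[tuple[int, int], int] = {}
    for p in pairs:
        counts[p] = counts.get(p, 0) + 1
    best = max(counts.items(), key=lambda kv: (kv[1], (-kv[0][0], -kv[0][1])))
    return ContactCluster(
        cluster_id=-1,
        points=sub.reset_index(drop=True),
        n_points=len(sub),
        max_ln_rho_product=float(ln_rho.max()),
        min_sumdle=float(sub["sumdle"].min()),
        dominant_pair=(int(best[0][0]), int(best[0][1])),
    )


def summarize_cluster(cluster: ContactCluster) -> dict:
    """Summary record of one contact cluster (recomputed from its points)."""
    fresh = _summarize(cluster.points)
    sub = cluster.points
    dom = sub[
        (sub["lig_serial"] == fresh.dominant_pair[0])
        & (sub["enz_serial"] == fresh.dominant_pair[1])
    ].iloc[0]
    return {
        "cluster_id": cluster.cluster_id,
        "n_points": fresh.n_points,
        "min_sumdle": fresh.min_sumdle,
        "max_ln_rho_product": fresh.max_ln_rho_product,
        "lig_serial": int(dom["lig_serial"]),
        "lig_name": str(dom["lig_name"]),
        "enz_serial": int(dom["enz_serial"]),
        "enz_name": str(dom["enz_name"]),
        "enz_resname": str(dom["enz_resname"]),
    }


def assign_cluster_ids(
    points: pd.DataFrame, clusters: list[ContactCluster]
) -> pd.DataFrame:
    """Return a copy of the point table with a cluster_id column.

    Points dropped by a strength floor get cluster_id -1.
    """
    out = points.copy()
    out["cluster_id"] = -1
    key = ["ix", "iy", "iz"]
    index = {tuple(t): i for i, t in enumerate(out[key].to_numpy(dtype=int))}
    for c in clusters:
        for t in c.points[key].to_numpy(dtype=int):
            out.loc[index[tuple(t)], "cluster_id"] = c.cluster_id
    return out


def write_clusters_tsv(clusters: list[ContactCluster], path: str | Path) -> None:
    cols = [
        "cluster_id", "n_points", "min_sumdle", "max_ln_rho_product",
        "lig_serial", "lig_name", "enz_serial", "enz_name", "enz_resname",
    ]
    lines = ["\t".join(cols)]
    for c in clusters:
        rec = summarize_cluster(c)
        lines.append(
            "\t".join(
                f"{rec[k]:.6g}" if isinstance(rec[k], float) else str(rec[k])
                for k in cols
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
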
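"""Symmetry-corrected RMSD between two poses of the same molecule.

Chemically equivalent atoms (the two oxygens of a carboxylate, the two
methyls of an isopropyl group, ...) make the naive in-order RMSD
overestimate the true deviation. The Hungarian variant finds, within each
element class, the one-to-one atom correspondence minimizing the total
squared distance, so symmetric swaps cost nothing. Poses are compared in
the frame they come in — docked and reference poses share the receptor
frame — and no superposition is applied.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .errors import EmptyPoseError, IncompatiblePosesError
from .structio import MoleculePose


@dataclass(frozen=True)
class RmsdResult:
    rmsd: float
    mapping: tuple[tuple[int, int], ...]  # (serial in a, serial in b) pairs
    variant: str
    excluded: frozenset[int] = frozenset()


def _included_atoms(pose: MoleculePose, exclude: frozenset[int], include_h: bool):
    atoms = [
        a
        for a in pose.atoms
        if a.serial not in exclude and (include_h or a.element != "H")
    ]
    if not atoms:
        raise EmptyPoseError("no atoms left after exclusion/hydrogen filtering")
    return atoms


def symmetry_corrected_rmsd(
    a: MoleculePose,
    b: MoleculePose,
    *,
    exclude: frozenset[int] | set[int] = frozenset(),
    variant: str = "hungarian",
    include_hydrogens: bool = False,
) -> RmsdResult:
    """RMSD between two poses sharing a Cartesian frame.

    variant "hungarian" solves a minimum-cost assignment within each
    element class; "naive" pairs atoms in input order. Hydrogens are
    excluded by default (their PDB positions are unreliable); ``exclude``
    drops atoms by serial from both poses, e.g. a substituent protruding
    out of the binding pocket.

    Raises :class:`IncompatiblePosesError` when the element multisets of
    the two poses differ after exclusion.
    """
    if variant not in ("hungarian", "naive"):
        raise ValueError("variant must be 'hungarian' or 'naive'")
    exclude = frozenset(exclude)
    atoms_a = _included_atoms(a, exclude, include_hydrogens)
    atoms_b = _included_atoms(b, exclude, include_hydrogens)
    count_a = Counter(x.element for x in atoms_a)
    count_b = Counter(x.element for x in atoms_b)
    if count_a != count_b:
        diff = {
            el: (count_a.get(el, 0), count_b.get(el, 0))
            for el in sorted(set(count_a) | set(count_b))
            if count_a.get(el, 0) != count_b.get(el, 0)
        }
        raise IncompatiblePosesError(
            f"element multisets differ (element: count_a, count_b): {diff}"
        )

    total_sq = 0.0
    n = 0
    mapping: list[tuple[int, int]] = []
    if variant == "naive":
        if len(atoms_a) != len(atoms_b):
            raise IncompatiblePosesError("poses differ in atom count")
        for xa, xb in zip(atoms_a, atoms_b):
            total_sq += float(np.sum((xa.coords - xb.coords) ** 2))
            mapping.append((xa.serial, xb.serial))
        n = len(atoms_a)
    else:
        for element in sorted(count_a):
            ga = [x for x in atoms_a if x.element == element]
            gb = [x for x in atoms_b if x.element == element]
            cost = cdist(
                np.array([x.coords for x in ga]),
                np.array([x.coords for x in gb]),
                "sqeuclidean",
            )
            rows, cols = linear_sum_assignment(cost)
            total_sq += float(cost[rows, cols].sum())
            mapping.extend((ga[i].serial, gb[j].serial) for i, j in zip(rows, cols))
            n += len(ga)
    return RmsdResult(
        rmsd=math.sqrt(total_sq / n),
        mapping=tuple(sorted(mapping)),
        variant=variant,
        excluded=exclude,
    )
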
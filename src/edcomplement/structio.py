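"""Structure I/O: read PDB files, split complexes into receptor and ligand.

Poses are kept in the input Cartesian frame; no superposition is performed
anywhere in the toolkit. Docked, minimized and crystallographic poses are
assumed to be pre-aligned against a common receptor frame.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import EmptyPoseError, FormatError, SelectionError, UnsupportedElementError

WATER_RESNAMES = frozenset({"HOH", "WAT", "DOD"})


@dataclass(eq=False)
class AtomRecord:
    """One atom: identity, element and Cartesian coordinates in Å.

    Equality is by object identity: two parses of the same file yield
    distinct records, and pose membership means this record object.
    """

    serial: int
    element: str
    atomic_number: int
    coords: np.ndarray
    name: str = ""
    resname: str = ""
    chain: str = ""
    resseq: int = 0
    is_hetero: bool = False
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        if self.atomic_number < 1:
            raise ValueError(f"atom {self.serial}: atomic_number must be >= 1")


@dataclass
class MoleculePose:
    """An ordered collection of atoms forming one pose of one molecule."""

    atoms: list[AtomRecord]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyPoseError(f"pose {self.label!r} has no atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array, Å."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def serials(self) -> list[int]:
        return [a.serial for a in self.atoms]

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([a.atomic_number for a in self.atoms], dtype=int)

    def heavy_atoms(self) -> "MoleculePose":
        heavy = [a for a in self.atoms if a.element != "H"]
        if not heavy:
            raise EmptyPoseError(f"pose {self.label!r} has no heavy atoms")
        return MoleculePose(heavy, label=self.label)

    def translated(self, shift: Sequence[float], label: str | None = None) -> "MoleculePose":
        shift = np.asarray(shift, dtype=float)
        atoms = [replace(a, coords=a.coords + shift) for a in self.atoms]
        return MoleculePose(atoms, label=self.label if label is None else label)


def _resolve_element(atom: gemmi.Atom, resname: str) -> tuple[str, int]:
    el = atom.element
    if el.atomic_number > 0:
        return el.name, el.atomic_number
    # Blank element column: infer from the atom name. A name whose first
    # character sits in PDB column 13 (no leading pad) may carry a two-letter
    # element symbol; otherwise the first alphabetic character is the element.
    padded = atom.padded_name or atom.name
    letters = re.sub(r"[^A-Za-z]", "", atom.name)
    if not letters:
        raise UnsupportedElementError(
            f"cannot resolve element for atom {atom.name!r} in residue {resname!r}"
        )
    if len(letters) >= 2 and padded and padded[0] != " ":
        two = letters[0].upper() + letters[1].lower()
        cand = gemmi.Element(two)
        if cand.atomic_number > 0:
            return cand.name, cand.atomic_number
    one = gemmi.Element(letters[0].upper())
    if one.atomic_number > 0:
        return one.name, one.atomic_number
    raise UnsupportedElementError(
        f"cannot resolve element for atom {atom.name!r} in residue {resname!r}"
    )


def _iter_model_atoms(model: gemmi.Model) -> Iterable[tuple[gemmi.Chain, gemmi.Residue, gemmi.Atom]]:
    for chain in model:
        for res in chain:
            for atom in res:
                yield chain, res, atom


def _select_altlocs(
    records: list[AtomRecord], which: str | None
) -> list[AtomRecord]:
    """Collapse alternate locations.

    ``which=None`` keeps, per (chain, resseq, atom name) site, the highest
    occupancy altloc with ties broken by altloc letter order. A specific
    letter keeps that conformer (plus all non-altloc atoms).
    """
    if which is not None:
        return [r for r in records if r.altloc in ("", which)]
    by_site: dict[tuple[str, int, str], AtomRecord] = {}
    order: list[tuple[str, int, str]] = []
    for r in records:
        key = (r.chain, r.resseq, r.name)
        if key not in by_site:
            by_site[key] = r
            order.append(key)
        else:
            cur = by_site[key]
            if (r.occupancy, _altloc_rank(r.altloc)) > (
                cur.occupancy,
                _altloc_rank(cur.altloc),
            ):
                by_site[key] = r
    return [by_site[k] for k in order]


def _altloc_rank(altloc: str) -> float:
    # earlier letters preferred at equal occupancy -> higher rank
    return 0.0 if not altloc else -ord(altloc)


def read_pdb(
    path: str | Path,
    model_index: int = 0,
    *,
    exclude_waters: bool = True,
    altloc: str | None = None,
    label: str | None = None,
) -> MoleculePose:
    """Read one model of a PDB file as a :class:`MoleculePose`.

    Parameters
    ----------
    path : str or Path
        PDB file with ATOM/HETATM records.
    model_index : int
        Which MODEL of a multi-model file to read (0-based).
    exclude_waters : bool
        Drop water residues (HOH/WAT/DOD). Default True.
    altloc : str or None
        ``None`` keeps the highest-occupancy alternate location per site
        (ties by letter order); a letter keeps that conformer only.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"no models found in {path}")
    if not 0 <= model_index < len(st):
        raise FormatError(
            f"model_index {model_index} out of range for {path} ({len(st)} models)"
        )
    model = st[model_index]
    records: list[AtomRecord] = []
    for chain, res, atom in _iter_model_atoms(model):
        if exclude_waters and res.name in WATER_RESNAMES:
            continue
        element, z = _resolve_element(atom, res.name)
        records.append(
            AtomRecord(
                serial=atom.serial,
                element=element,
                atomic_number=z,
                coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                name=atom.name,
                resname=res.name,
                chain=chain.name,
                resseq=res.seqid.num,
                is_hetero=res.het_flag == "H",
                altloc="" if atom.altloc in ("", " ", "\0") else atom.altloc,
                occupancy=atom.occ,
            )
        )
    if not records:
        raise FormatError(f"no atoms read from {path} (model {model_index})")
    records = _select_altlocs(records, altloc)
    return MoleculePose(records, label=label or path.stem)


def altloc_poses(
    path: str | Path, model_index: int = 0, *, exclude_waters: bool = True
) -> list[MoleculePose]:
    """One pose per alternate-location letter present in the file.

    Alternate conformations are treated as separate complexes. A file
    without altlocs yields a single pose.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    letters = sorted(
        {
            atom.altloc
            for _, _, atom in _iter_model_atoms(st[model_index])
            if atom.altloc not in ("", " ", "\0")
        }
    )
    if not letters:
        return [read_pdb(path, model_index, exclude_waters=exclude_waters)]
    return [
        read_pdb(
            path,
            model_index,
            exclude_waters=exclude_waters,
            altloc=letter,
            label=f"{path.stem}_alt{letter}",
        )
        for letter in letters
    ]


def write_pdb(pose: MoleculePose, path: str | Path) -> None:
    """Write a pose as a single-model PDB file (coordinates to 3 decimals)."""
    st = gemmi.Structure()
    st.name = pose.label or "pose"
    model = gemmi.Model("1")
    # gemmi's add_residue/add_chain copy their argument, so residues and
    # chains must be fully populated before being added
    grouped: dict[str, dict[tuple[int, str], list[AtomRecord]]] = {}
    for rec in pose.atoms:
        cname = rec.chain or "A"
        grouped.setdefault(cname, {}).setdefault(
            (rec.resseq or 1, rec.resname or "UNK"), []
        ).append(rec)
    for cname, residues in grouped.items():
        chain = gemmi.Chain(cname)
        for (resseq, resname), recs in residues.items():
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resseq, " ")
            res.het_flag = "H" if recs[0].is_hetero else "A"
            for rec in recs:
                atom = gemmi.Atom()
                atom.name = rec.name or rec.element
                atom.element = gemmi.Element(rec.element)
                atom.pos = gemmi.Position(*rec.coords)
                atom.serial = rec.serial
                atom.occ = rec.occupancy
                atom.altloc = rec.altloc or "\0"
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


@dataclass
class LigandSelector:
    """Match atoms by residue name and/or chain and/or serial range."""

    resname: str | None = None
    chain: str | None = None
    serial_range: tuple[int, int] | None = None

    @classmethod
    def parse(cls, expr: str) -> "LigandSelector":
        """Parse ``"resname=LIG,chain=A,serial=10-42"`` style expressions."""
        sel = cls()
        for part in expr.split(","):
            part = part.strip()
            if not part:
                continue
            if "=" not in part:
                raise SelectionError(f"bad selector clause {part!r}")
            key, _, value = part.partition("=")
            key = key.strip().lower()
            value = value.strip()
            if key == "resname":
                sel.resname = value
            elif key == "chain":
                sel.chain = value
            elif key == "serial":
                lo, _, hi = value.partition("-")
                sel.serial_range = (int(lo), int(hi or lo))
            else:
                raise SelectionError(f"unknown selector key {key!r}")
        if sel.resname is None and sel.chain is None and sel.serial_range is None:
            raise SelectionError(f"empty selector expression {expr!r}")
        return sel

    def matches(self, atom: AtomRecord) -> bool:
        if self.resname is not None and atom.resname != self.resname:
            return False
        if self.chain is not None and atom.chain != self.chain:
            return False
        if self.serial_range is not None:
            lo, hi = self.serial_range
            if not lo <= atom.serial <= hi:
                return False
        return True


def split_complex(
    pose: MoleculePose, selector: LigandSelector | str
) -> tuple[MoleculePose, MoleculePose]:
    """Partition a complex into (receptor, ligand) by a ligand selector.

    The partition is exact and disjoint: every non-water atom lands in
    exactly one of the two poses. Waters, if still present, are dropped.
    """
    if isinstance(selector, str):
        selector = LigandSelector.parse(selector)
    ligand, receptor = [], []
    for atom in pose.atoms:
        if atom.resname in WATER_RESNAMES:
            continue
        (ligand if selector.matches(atom) else receptor).append(atom)
    if not ligand:
        raise SelectionError("ligand selector matched no atoms")
    if not receptor:
        raise SelectionError("ligand selector matched every atom (degenerate split)")
    return (
        MoleculePose(receptor, label=f"{pose.label}_receptor"),
        MoleculePose(ligand, label=f"{pose.label}_ligand"),
    )
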
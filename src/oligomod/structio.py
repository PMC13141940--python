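"""Atomic structure container and PDB/mmCIF input/output.

The in-memory model is a plain chain → residue → atom hierarchy carrying
author residue numbering (the numbering used throughout the structural
literature on these proteins). Parsing and serialization are delegated to
gemmi; this module enforces the polymer-protein policy on top of it:

* only amino-acid polymer residues are kept (waters, ligands, ions dropped);
* hydrogens are always dropped (all downstream cutoffs are heavy-atom based);
* alternate locations are resolved to altloc "A" or, failing that, the
  highest-occupancy conformer (ties broken by file order);
* for multi-model files (NMR-style) only the first model is read;
* mmCIF author (auth_) identifiers are used for chains and residue numbers.
"""

from __future__ import annotations

import gzip
import logging
import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import gemmi
import numpy as np

from .errors import EmptyStructureError, FormatError

log = logging.getLogger(__name__)

_CHAIN_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits


@dataclass
class Atom:
    """A single heavy atom with Cartesian coordinates in Angstrom."""

    name: str
    element: str
    position: np.ndarray  # shape (3,), float64
    occupancy: float = 1.0
    altloc: str = ""
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be 3 finite floats")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} not in [0,1]")


@dataclass
class Residue:
    number: int
    name: str
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, number: int, insertion_code: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.number == number and r.insertion_code == insertion_code:
                return r
        return None

    @property
    def residue_numbers(self) -> list[int]:
        return [r.number for r in self.residues]


@dataclass
class StructureModel:
    """Hierarchical coordinate set: chains → residues → atoms."""

    identifier: str = ""
    chains: list[Chain] = field(default_factory=list)

    def chain(self, chain_id: str) -> Optional[Chain]:
        for c in self.chains:
            if c.id == chain_id:
                return c
        return None

    def iter_atoms(self) -> Iterator[tuple[Chain, Residue, Atom]]:
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    def coords(self) -> np.ndarray:
        """All atom positions, (n_atoms, 3), in hierarchy order."""
        pts = [a.position for _, _, a in self.iter_atoms()]
        return np.array(pts, dtype=float) if pts else np.empty((0, 3))

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        atoms = [a for _, _, a in self.iter_atoms()]
        if xyz.shape != (len(atoms), 3):
            raise ValueError(f"expected coordinates of shape ({len(atoms)}, 3)")
        for a, p in zip(atoms, xyz):
            a.position = p.copy()

    def ca_coords(self, chain_id: str, residue_numbers: Optional[Iterable[int]] = None) -> np.ndarray:
        """CA positions of one chain, optionally restricted to residue numbers."""
        chain = self.chain(chain_id)
        if chain is None:
            return np.empty((0, 3))
        wanted = None if residue_numbers is None else set(residue_numbers)
        pts = []
        for r in chain.residues:
            if wanted is not None and r.number not in wanted:
                continue
            ca = r.atom("CA")
            if ca is not None:
                pts.append(ca.position)
        return np.array(pts, dtype=float) if pts else np.empty((0, 3))

    def copy(self) -> "StructureModel":
        return StructureModel(
            identifier=self.identifier,
            chains=[
                Chain(
                    id=c.id,
                    residues=[
                        Residue(
                            number=r.number,
                            name=r.name,
                            insertion_code=r.insertion_code,
                            atoms=[replace(a, position=a.position.copy()) for a in r.atoms],
                        )
                        for r in c.residues
                    ],
                )
                for c in self.chains
            ],
        )


# ---------------------------------------------------------------------------
# reading

def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: altloc 'A', else highest occupancy."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name in order:
        group = by_name[name]
        if len(group) == 1:
            out.append(group[0])
            continue
        pick = next((a for a in group if a.altloc in ("", "A")), None)
        if pick is None:
            pick = max(group, key=lambda a: a.occupancy)  # stable: first max wins
        out.append(pick)
    return out


def _from_gemmi(st: gemmi.Structure, identifier: str) -> StructureModel:
    st.setup_entities()
    if len(st) > 1:
        log.warning("multi-model file: keeping first model only")
    model = StructureModel(identifier=identifier)
    gm = st[0]
    for gchain in gm:
        chain = Chain(id=gchain.name)
        for gres in gchain:
            info = gemmi.find_tabulated_residue(gres.name)
            if info is None or not info.is_amino_acid():
                continue
            if gres.het_flag == "H" and (info is None or not info.is_amino_acid()):
                continue
            if gres.seqid.icode.strip():
                log.warning("insertion code %r at %s %s%d", gres.seqid.icode,
                            gchain.name, gres.name, gres.seqid.num)
            atoms = []
            for ga in gres:
                if ga.element.is_hydrogen:
                    continue
                atoms.append(
                    Atom(
                        name=ga.name,
                        element=ga.element.name.upper(),
                        position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=min(max(ga.occ, 0.0), 1.0),
                        altloc=(ga.altloc if ga.altloc != "\x00" else "").strip(),
                        bfactor=ga.b_iso,
                    )
                )
            atoms = _resolve_altlocs(atoms)
            if atoms:
                chain.residues.append(
                    Residue(
                        number=gres.seqid.num,
                        name=gres.name,
                        insertion_code=gres.seqid.icode.strip(),
                        atoms=atoms,
                    )
                )
        if chain.residues:
            model.chains.append(chain)
    return model


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel (protein polymer only).

    Parameters
    ----------
    path:
        Plain or gzip-compressed coordinate file.
    format:
        ``"pdb"``, ``"mmcif"`` or ``"auto"`` (determined from the suffix).

    Raises
    ------
    FormatError
        If the file cannot be parsed in the declared format.
    EmptyStructureError
        If the file contains no polymer protein atoms.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    fmt = format.lower()
    if fmt == "auto":
        name = path.name.lower().removesuffix(".gz")
        fmt = "mmcif" if name.endswith((".cif", ".mmcif")) else "pdb"
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.cif.read(str(path))
            st = gemmi.make_structure_from_block(st.sole_block())
        else:
            raise FormatError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    model = _from_gemmi(st, identifier=path.stem.removesuffix(".pdb").removesuffix(".cif"))
    if model.n_atoms == 0:
        raise EmptyStructureError(f"{path}: no polymer protein atoms found")
    return model


# ---------------------------------------------------------------------------
# writing

def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.identifier or "MODEL"
    gm = gemmi.Model("1")
    for chain in model.chains:
        gc = gemmi.Chain(chain.id)
        for res in chain.residues:
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element.capitalize())
                ga.pos = gemmi.Position(*a.position)
                ga.occ = a.occupancy
                ga.b_iso = a.bfactor
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a StructureModel as a standard PDB file.

    Round trip guarantee: chain ids, residue numbers/names, atom names and
    coordinates (to 3 decimals) survive read_structure(write_structure(m)).
    """
    if model.n_atoms == 0:
        raise EmptyStructureError("refusing to write an empty structure")
    if len(model.chains) > len(_CHAIN_ALPHABET):
        raise ValueError(
            f"{len(model.chains)} chains exceed the {len(_CHAIN_ALPHABET)} "
            "single-character chain ids of the PDB format"
        )
    for c in model.chains:
        for r in c.residues:
            if r.number > 9999 or r.number < -999:
                raise ValueError(
                    f"residue number {r.number} does not fit the PDB format"
                )
    st = _to_gemmi(model)
    doc = st.make_pdb_string()
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "wt") as fh:
            fh.write(doc)
    else:
        path.write_text(doc)


# ---------------------------------------------------------------------------
# selection

def select(
    model: StructureModel,
    chain_ids: Optional[Iterable[str]] = None,
    residue_range: Optional[Sequence[int]] = None,
    atom_names: Optional[Iterable[str]] = None,
) -> StructureModel:
    """Sub-structure matching all given filters; ordering preserved.

    ``residue_range`` is an inclusive ``[lo, hi]`` pair in author numbering.
    An empty result is a valid value, not an error.
    """
    chain_set = None if chain_ids is None else set(chain_ids)
    atom_set = None if atom_names is None else set(atom_names)
    lo, hi = (None, None) if residue_range is None else (residue_range[0], residue_range[1])
    out = StructureModel(identifier=model.identifier)
    for chain in model.chains:
        if chain_set is not None and chain.id not in chain_set:
            continue
        new_chain = Chain(id=chain.id)
        for res in chain.residues:
            if lo is not None and not (lo <= res.number <= hi):
                continue
            atoms = [replace(a, position=a.position.copy()) for a in res.atoms
                     if atom_set is None or a.name in atom_set]
            if atoms:
                new_chain.residues.append(
                    Residue(res.number, res.name, res.insertion_code, atoms)
                )
        if new_chain.residues:
            out.chains.append(new_chain)
    return out
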
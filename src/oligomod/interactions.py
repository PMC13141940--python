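"""Inter-chain interaction analysis: buried surface area, salt bridges,
hydrophobic contacts.

SASA is computed with a deterministic Shrake–Rupley scheme: every atom is
surrounded by the same golden-section (Fibonacci) spiral lattice of test
points on its solvent-expanded sphere, and a point counts as accessible when
it lies outside every neighbouring expanded sphere. With a fixed point count
the result is bit-reproducible. Buried interface area follows the usual
convention: half the solvent-accessible area lost on complex formation,

    buried = (SASA(A) + SASA(B) - SASA(AB)) / 2.

Salt bridges are close-range ion pairs between basic side-chain nitrogens
(Arg NE/NH1/NH2, Lys NZ, optionally His ND1/NE2) and acidic side-chain
oxygens (Asp OD1/OD2, Glu OE1/OE2); one record is kept per residue pair, at
the minimum atom distance. Hydrophobic contacts pair apolar side-chain
carbons (Ala, Val, Leu, Ile, Met, Phe, Trp, Pro); glycine participates via
its CA. Only inter-chain contacts are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from ._tables import (
    ACIDIC_OXYGENS,
    BACKBONE_ATOMS,
    BASIC_NITROGENS,
    HISTIDINE_NITROGENS,
    HYDROPHOBIC_RESIDUES,
    VDW_RADII,
)
from .errors import RadiusLookupError
from .structio import StructureModel, select

DEFAULT_PROBE_RADIUS = 1.4  # A, water probe
DEFAULT_SASA_POINTS = 960
DEFAULT_SALT_BRIDGE_CUTOFF = 4.0  # A, N-O
DEFAULT_HYDROPHOBIC_CUTOFF = 4.5  # A, C-C


@dataclass
class InteractionRecord:
    kind: str  # "salt_bridge" | "hydrophobic"
    chain1: str
    residue1: int
    resname1: str
    atom1: str
    chain2: str
    residue2: int
    resname2: str
    atom2: str
    distance: float

    def as_tsv_row(self) -> str:
        return "\t".join(
            str(x)
            for x in (
                self.kind, self.chain1, self.residue1, self.resname1, self.atom1,
                self.chain2, self.residue2, self.resname2, self.atom2,
                f"{self.distance:.3f}",
            )
        )


@dataclass
class InterfaceReport:
    chain_pair: tuple[str, str]
    buried_area: float  # A^2, half-dSASA over residue_range_used
    buried_area_full: float  # A^2, half-dSASA over whole chains
    residue_range_used: Optional[tuple[int, int]]
    salt_bridges: list[InteractionRecord] = field(default_factory=list)
    hydrophobic_residues: dict[str, set[int]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "chain_pair": list(self.chain_pair),
            "buried_area": self.buried_area,
            "buried_area_full": self.buried_area_full,
            "residue_range_used": list(self.residue_range_used)
            if self.residue_range_used else None,
            "salt_bridges": [vars(r) for r in self.salt_bridges],
            "hydrophobic_residues": {
                k: sorted(v) for k, v in self.hydrophobic_residues.items()
            },
        }


# ---------------------------------------------------------------------------
# SASA

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic golden-section spiral lattice of n unit vectors."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i  # golden angle increments
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def atom_radii(model: StructureModel) -> np.ndarray:
    """Van der Waals radius per atom, in model iteration order."""
    radii = []
    missing = []
    for chain, res, atom in model.iter_atoms():
        r = VDW_RADII.get(atom.element.upper())
        if r is None:
            missing.append(f"{chain.id}/{res.name}{res.number}/{atom.name} ({atom.element})")
        else:
            radii.append(r)
    if missing:
        raise RadiusLookupError("no van der Waals radius for: " + ", ".join(missing))
    return np.asarray(radii)


def compute_sasa(
    model: StructureModel,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_SASA_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), Shrake–Rupley.

    Deterministic for a fixed ``n_points`` (fixed spiral lattice, no
    randomness). The sum over atoms is the molecular SASA.
    """
    coords = model.coords()
    if coords.shape[0] == 0:
        return np.empty(0)
    radii = atom_radii(model) + probe_radius
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    areas = np.zeros(len(coords))
    for i, (c, r) in enumerate(zip(coords, radii)):
        pts = c + r * sphere
        neighbours = [j for j in tree.query_ball_point(c, r + max_r) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 > radii[j] ** 2
        areas[i] = 4.0 * np.pi * r * r * accessible.sum() / n_points
    return areas


def _chain_sasa_sum(model: StructureModel, **kw) -> float:
    return float(compute_sasa(model, **kw).sum())


def interface_area(
    model: StructureModel,
    chain1: str,
    chain2: str,
    residue_range: Optional[Sequence[int]] = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_SASA_POINTS,
) -> float:
    """Buried interface area (A^2) between two chains: half the SASA lost on
    complex formation, optionally restricted to a residue interval."""
    sub = select(model, {chain1, chain2}, residue_range)
    a = select(sub, {chain1})
    b = select(sub, {chain2})
    if a.n_atoms == 0 or b.n_atoms == 0:
        return 0.0
    kw = dict(probe_radius=probe_radius, n_points=n_points)
    buried = _chain_sasa_sum(a, **kw) + _chain_sasa_sum(b, **kw) - _chain_sasa_sum(sub, **kw)
    return max(buried / 2.0, 0.0)


# ---------------------------------------------------------------------------
# contact detection

def _collect_atoms(model: StructureModel, wanted: dict[str, tuple[str, ...]]):
    """(chain, resnum, resname, atomname, xyz) for atoms named in ``wanted``."""
    out = []
    for chain, res, atom in model.iter_atoms():
        names = wanted.get(res.name)
        if names and atom.name in names:
            out.append((chain.id, res.number, res.name, atom.name, atom.position))
    return out


def _min_distance_records(
    kind: str, group1, group2, cutoff: float
) -> list[InteractionRecord]:
    """One record per inter-chain residue pair, at the minimum atom distance."""
    best: dict[tuple, InteractionRecord] = {}
    if not group1 or not group2:
        return []
    xyz2 = np.array([g[4] for g in group2])
    tree = cKDTree(xyz2)
    for c1, n1, rn1, a1, p1 in group1:
        for j in tree.query_ball_point(p1, cutoff):
            c2, n2, rn2, a2, p2 = group2[j]
            if c1 == c2:
                continue
            d = float(np.linalg.norm(p1 - p2))
            # canonical key: unordered chain/residue pair
            key = tuple(sorted([(c1, n1), (c2, n2)]))
            rec = InteractionRecord(kind, c1, n1, rn1, a1, c2, n2, rn2, a2, d)
            if key not in best or d < best[key].distance:
                best[key] = rec
    return sorted(
        best.values(), key=lambda r: (r.chain1, r.residue1, r.chain2, r.residue2)
    )


def find_salt_bridges(
    model: StructureModel,
    cutoff: float = DEFAULT_SALT_BRIDGE_CUTOFF,
    include_histidine: bool = False,
) -> list[InteractionRecord]:
    """Inter-chain salt bridges (basic N within ``cutoff`` of acidic O)."""
    basic = dict(BASIC_NITROGENS)
    if include_histidine:
        basic.update(HISTIDINE_NITROGENS)
    nitrogens = _collect_atoms(model, basic)
    oxygens = _collect_atoms(model, ACIDIC_OXYGENS)
    return _min_distance_records("salt_bridge", nitrogens, oxygens, cutoff)


def find_hydrophobic_contacts(
    model: StructureModel,
    cutoff: float = DEFAULT_HYDROPHOBIC_CUTOFF,
) -> tuple[list[InteractionRecord], dict[str, set[int]]]:
    """Inter-chain apolar carbon contacts and the participating residues.

    Returns the contact records plus, per chain, the set of residue numbers
    with at least one contact.
    """
    apolar = []
    for chain, res, atom in model.iter_atoms():
        if res.name in HYDROPHOBIC_RESIDUES:
            # side-chain carbons only (CB and beyond)
            if atom.element.upper() == "C" and atom.name not in BACKBONE_ATOMS:
                apolar.append((chain.id, res.number, res.name, atom.name, atom.position))
        elif res.name == "GLY" and atom.name == "CA":
            apolar.append((chain.id, res.number, res.name, atom.name, atom.position))
    records = _min_distance_records("hydrophobic", apolar, apolar, cutoff)
    participating: dict[str, set[int]] = {}
    for r in records:
        participating.setdefault(r.chain1, set()).add(r.residue1)
        participating.setdefault(r.chain2, set()).add(r.residue2)
    return records, participating


def dimer_report(
    model: StructureModel,
    pairs: Iterable[tuple[str, str]],
    residue_range: Optional[Sequence[int]] = None,
    salt_bridge_cutoff: float = DEFAULT_SALT_BRIDGE_CUTOFF,
    hydrophobic_cutoff: float = DEFAULT_HYDROPHOBIC_CUTOFF,
    n_points: int = DEFAULT_SASA_POINTS,
) -> list[InterfaceReport]:
    """Combined interface report (area, salt bridges, hydrophobics) per pair."""
    reports = []
    for c1, c2 in pairs:
        sub = select(model, {c1, c2})
        sb = find_salt_bridges(sub, salt_bridge_cutoff)
        _, hydro = find_hydrophobic_contacts(sub, hydrophobic_cutoff)
        reports.append(
            InterfaceReport(
                chain_pair=(c1, c2),
                buried_area=interface_area(model, c1, c2, residue_range, n_points=n_points),
                buried_area_full=interface_area(model, c1, c2, None, n_points=n_points),
                residue_range_used=tuple(residue_range) if residue_range else None,
                salt_bridges=sb,
                hydrophobic_residues=hydro,
            )
        )
    return reports


def records_to_tsv(records: Iterable[InteractionRecord]) -> str:
    header = "kind\tchain1\tresidue1\tresname1\tatom1\tchain2\tresidue2\tresname2\tatom2\tdistance"
    return "\n".join([header, *(r.as_tsv_row() for r in records)])
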
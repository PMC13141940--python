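"""Synthetic structures and scattering data with known ground truth.

Every generator is deterministic under a fixed seed and emulates a feature
of the real study system so that each pipeline stage can be exercised
without downloads:

* ideal α-helices, optionally with a bend at a chosen residue — the fold of
  the crystallized N-terminal domain (two helices with a bend near the
  middle);
* antiparallel two-helix dimers — the terminal-site coiled-coil;
* rigid-transformed, coordinate-noised copies — superposition fixtures;
* bead-filled spheres — analytic bodies for scattering oracles;
* simulated size-exclusion elution series with a Gaussian concentration
  peak over a constant buffer — SEC-SAXS reduction fixtures.

Helix geometry uses textbook values: 1.5 A rise and 100° twist per residue,
2.3 A CA helix radius. Backbone N, C and O atoms are placed on companion
helical paths with standard radial/axial offsets; side chains are not
generated (interaction-detection fixtures place explicit side-chain atoms
at specified geometry instead).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import SpecError
from .saxs import FrameSeries, ScatteringProfile
from .structio import Atom, Chain, Residue, StructureModel
from .superpose import RigidTransform
from ._tables import AA1_TO_3


@dataclass
class HelixSpec:
    n_residues: int
    rise_per_residue: float = 1.5  # A
    twist_per_residue: float = 100.0  # degrees
    ca_radius: float = 2.3  # A
    bend_residue: Optional[int] = None
    bend_angle: Optional[float] = None  # degrees
    sequence: Optional[str] = None

    def validate(self) -> None:
        if self.n_residues < 3:
            raise SpecError("helix needs >= 3 residues")
        if self.bend_residue is not None and not (0 < self.bend_residue < self.n_residues):
            raise SpecError("bend_residue must be inside the chain")
        if self.sequence is not None and len(self.sequence) != self.n_residues:
            raise SpecError("sequence length must equal n_residues")


@dataclass
class NoiseSpec:
    seed: int = 0
    coordinate_sigma: float = 0.0  # A
    intensity_relative_sigma: float = 0.0

    def validate(self) -> None:
        if self.coordinate_sigma < 0 or self.intensity_relative_sigma < 0:
            raise SpecError("noise sigmas must be >= 0")


# backbone atoms on companion helices: (radius A, phase offset deg, z offset A)
_BACKBONE_HELIX = {
    "N": (1.56, -28.0, -0.90),
    "CA": (None, 0.0, 0.0),  # radius from spec
    "C": (1.66, 26.0, 0.75),
    "O": (1.95, 25.0, 2.00),
}
_BACKBONE_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O"}


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def make_helix(spec: HelixSpec, chain_id: str = "A", first_residue: int = 1) -> StructureModel:
    """Ideal α-helix along z with N/CA/C/O backbone; optional axis bend."""
    spec.validate()
    model = StructureModel(identifier="synthetic_helix")
    chain = Chain(id=chain_id)
    seq = spec.sequence.upper() if spec.sequence else "A" * spec.n_residues
    twist = np.radians(spec.twist_per_residue)
    for i in range(spec.n_residues):
        resname = AA1_TO_3.get(seq[i], "ALA")
        res = Residue(number=first_residue + i, name=resname)
        for atom_name, (radius, dphi, dz) in _BACKBONE_HELIX.items():
            r = spec.ca_radius if radius is None else radius
            phi = i * twist + np.radians(dphi)
            pos = np.array(
                [r * np.cos(phi), r * np.sin(phi), i * spec.rise_per_residue + dz]
            )
            res.atoms.append(Atom(name=atom_name, element=_BACKBONE_ELEMENTS[atom_name], position=pos))
        chain.residues.append(res)
    model.chains.append(chain)

    if spec.bend_residue is not None and spec.bend_angle:
        # rotate the distal segment about an in-plane axis through the bend CA
        pivot_pos = chain.residues[spec.bend_residue - 1].atom("CA").position.copy()
        R = _rotation_about_axis(np.array([1.0, 0.0, 0.0]), spec.bend_angle)
        for res in chain.residues[spec.bend_residue:]:
            for a in res.atoms:
                a.position = R @ (a.position - pivot_pos) + pivot_pos
    return model


def make_antiparallel_dimer(
    spec: HelixSpec, axial_offset: float = 0.0, interhelix_distance: float = 10.0
) -> StructureModel:
    """Two-chain antiparallel helix dimer (chains A and B).

    Chain B is chain A rotated 180° about an axis perpendicular to the helix
    (z) axis, then translated ``interhelix_distance`` along x and
    ``axial_offset`` along z. Deterministic.
    """
    if interhelix_distance <= 0:
        raise SpecError("interhelix_distance must be > 0")
    a = make_helix(spec, chain_id="A")
    b = make_helix(spec, chain_id="B")
    R = _rotation_about_axis(np.array([1.0, 0.0, 0.0]), 180.0)
    centroid = a.coords().mean(axis=0)
    coords = (b.coords() - centroid) @ R.T + centroid
    coords[:, 0] += interhelix_distance
    coords[:, 2] += axial_offset
    b.set_coords(coords)
    return StructureModel(identifier="synthetic_dimer", chains=[a.chains[0], b.chains[0]])


def make_bead_sphere(radius: float, n_beads: int = 5000, seed: int = 0) -> StructureModel:
    """Beads uniform in a ball of the given radius (rejection sampling).

    Unit-weight pseudo-atoms (element "X"); the analytic radius of gyration
    of the underlying density is sqrt(3/5)·R.
    """
    if n_beads < 100:
        raise SpecError("need at least 100 beads")
    rng = np.random.default_rng(seed)
    pts = []
    while len(pts) < n_beads:
        cand = rng.uniform(-radius, radius, size=(2 * n_beads, 3))
        keep = cand[(cand**2).sum(axis=1) <= radius**2]
        pts.extend(keep.tolist())
    pts = np.array(pts[:n_beads])
    chain = Chain(id="A")
    # beads grouped into pseudo-residues to keep PDB serialization valid
    for i, p in enumerate(pts):
        res = Residue(number=i + 1, name="GLY")
        res.atoms.append(Atom(name="CA", element="X", position=np.asarray(p)))
        chain.residues.append(res)
    return StructureModel(identifier=f"bead_sphere_r{radius:g}", chains=[chain])


def simulate_sec_series(
    particle_profile: ScatteringProfile,
    n_frames: int = 303,
    peak_center: float = 139.0,
    peak_width: float = 8.0,
    buffer_level: float = 10.0,
    noise: NoiseSpec = NoiseSpec(),
) -> tuple[FrameSeries, np.ndarray]:
    """Simulated size-exclusion elution series of scattering frames.

    Frame i = buffer_level + exp(-(i-center)²/(2·width²)) · particle + noise.
    Returns the series and the ground-truth concentration trace. The default
    frame count and peak position emulate a continuous-collection SEC-SAXS
    run with the elution peak near frame 139.
    """
    noise.validate()
    if n_frames <= peak_center:
        raise SpecError("peak_center must lie inside the frame range")
    rng = np.random.default_rng(noise.seed)
    q = particle_profile.q
    conc = np.exp(-((np.arange(n_frames) - peak_center) ** 2) / (2.0 * peak_width**2))
    frames = []
    for i in range(n_frames):
        clean = buffer_level + conc[i] * particle_profile.intensity
        sigma = np.maximum(noise.intensity_relative_sigma * np.abs(clean), 1e-12)
        noisy = clean + rng.normal(0.0, 1.0, size=len(q)) * sigma if (
            noise.intensity_relative_sigma > 0
        ) else clean.copy()
        frames.append(
            ScatteringProfile(
                q.copy(), noisy,
                sigma if noise.intensity_relative_sigma > 0 else None,
            )
        )
    return FrameSeries(frames=frames), conc


def perturb(
    model: StructureModel, transform: RigidTransform, noise: NoiseSpec = NoiseSpec()
) -> StructureModel:
    """Apply a rigid transform, then i.i.d. Gaussian coordinate noise."""
    noise.validate()
    out = model.copy()
    coords = transform.apply(out.coords())
    if noise.coordinate_sigma > 0:
        rng = np.random.default_rng(noise.seed)
        coords = coords + rng.normal(0.0, noise.coordinate_sigma, size=coords.shape)
    out.set_coords(coords)
    return out
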
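"""Least-squares rigid-body superposition (Kabsch) and RMSD.

The SVD formulation with determinant sign correction is used, which
guarantees a proper rotation (no reflection). RMSD values are always the
post-superposition minimum, matching the convention of standard molecular
graphics tools. Chains are paired residue-by-residue on shared author
residue numbers, CA atoms only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np

from .errors import ConditioningError, PairingError
from .structio import StructureModel

#: smallest/largest covariance singular-value ratio below which the point
#: set is treated as collinear (rotation not uniquely determined)
DEGENERACY_RATIO = 1e-10


@dataclass
class RigidTransform:
    """Proper rotation + translation, mapping x to R @ x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        R = self.rotation
        if R.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation matrix is not proper (det != +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def rotation_angle(self) -> float:
        """Rotation angle in degrees (axis-angle magnitude)."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_pairs: int


def kabsch_fit(mobile: np.ndarray, target: np.ndarray) -> SuperpositionResult:
    """Optimal proper rigid motion minimizing RMSD of mobile onto target.

    Parameters
    ----------
    mobile, target:
        Paired coordinate arrays of identical shape (n, 3), n >= 3.

    Raises
    ------
    PairingError
        If the arrays differ in length or have fewer than 3 points.
    ConditioningError
        If the point set is collinear (rotation underdetermined).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape != target.shape:
        raise PairingError(
            f"coordinate sets must be paired (n, 3) arrays; got {mobile.shape} vs {target.shape}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise PairingError(f"need >= 3 paired atoms, got {n}")

    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    P = mobile - mc
    Q = target - tc
    H = P.T @ Q  # covariance
    U, S, Vt = np.linalg.svd(H)
    if S[0] <= 0 or S[1] < DEGENERACY_RATIO * S[0]:
        raise ConditioningError("collinear or degenerate point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    transform = RigidTransform(R, t)
    diff = transform.apply(mobile) - target
    rmsd = float(np.sqrt((diff * diff).sum() / n))
    return SuperpositionResult(transform=transform, rmsd=rmsd, n_pairs=n)


def apply_transform(model: StructureModel, t: RigidTransform) -> StructureModel:
    """Return a copy of the model with every atom mapped x -> R x + t."""
    out = model.copy()
    coords = out.coords()
    if coords.size:
        out.set_coords(t.apply(coords))
    return out


def chain_pair_rmsd(
    model: StructureModel,
    ref_chain: str,
    other_chains: Iterable[str],
) -> dict[str, float]:
    """Minimized CA RMSD of each chain against a reference chain.

    Atoms are paired by the intersection of author residue numbers ("common
    CA atomic pairs"); each pair is independently superposed with
    :func:`kabsch_fit`. Chains sharing fewer than 3 residues raise a
    PairingError only for themselves; results for the others are returned.
    """
    ref = model.chain(ref_chain)
    if ref is None:
        raise PairingError(f"reference chain {ref_chain!r} not in model")
    ref_numbers = {r.number for r in ref.residues if r.atom("CA") is not None}
    out: dict[str, float] = {}
    errors: dict[str, str] = {}
    for cid in other_chains:
        other = model.chain(cid)
        if other is None:
            errors[cid] = "chain absent"
            continue
        common = sorted(
            ref_numbers & {r.number for r in other.residues if r.atom("CA") is not None}
        )
        if len(common) < 3:
            errors[cid] = f"only {len(common)} common CA residues"
            continue
        a = model.ca_coords(ref_chain, common)
        b = model.ca_coords(cid, common)
        out[cid] = kabsch_fit(b, a).rmsd
    if errors and not out:
        raise PairingError("; ".join(f"{k}: {v}" for k, v in errors.items()))
    return out
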
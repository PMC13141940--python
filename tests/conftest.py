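"""Shared fixtures: synthetic structures, oracles, accession loading."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from oligomod.structio import Atom, Chain, Residue, StructureModel

ACCESSION_DIR = Path(__file__).resolve().parent.parent / "data" / "accessions"


# ---------------------------------------------------------------------------
# independent quaternion superposition oracle (test-only)

def quaternion_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    """Minimum RMSD via the quaternion characteristic-polynomial method.

    Independent of the SVD route: builds the 4x4 key matrix from the
    covariance of the centered point sets; the largest eigenvalue lambda
    gives rmsd = sqrt((G_a + G_b - 2*lambda) / n). Proper rotations only.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    n = len(mobile)
    P = mobile - mobile.mean(axis=0)
    Q = target - target.mean(axis=0)
    ga = float((P * P).sum())
    gb = float((Q * Q).sum())
    M = P.T @ Q
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = float(np.linalg.eigvalsh(K)[-1])
    return float(np.sqrt(max(ga + gb - 2.0 * lam, 0.0) / n))


@pytest.fixture(scope="session")
def quaternion_oracle():
    return quaternion_rmsd


# ---------------------------------------------------------------------------
# hand-built residues for contact-detection fixtures

def make_arg(chain_resnum: tuple[str, int], cz_position, direction=(1.0, 0.0, 0.0)):
    """Arginine with explicit guanidinium atoms around a CZ position."""
    cz = np.asarray(cz_position, float)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    perp = np.array([-d[1], d[0], 0.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    atoms = [
        Atom("CA", "C", cz - 4.0 * d),
        Atom("CB", "C", cz - 3.0 * d),
        Atom("CD", "C", cz - 2.0 * d),
        Atom("NE", "N", cz - 1.3 * d),
        Atom("CZ", "C", cz),
        Atom("NH1", "N", cz + 1.3 * (0.5 * d + 0.87 * perp)),
        Atom("NH2", "N", cz + 1.3 * (0.5 * d - 0.87 * perp)),
    ]
    return Residue(number=chain_resnum[1], name="ARG", atoms=atoms)


def make_glu(chain_resnum: tuple[str, int], cd_position, direction=(1.0, 0.0, 0.0)):
    """Glutamate with explicit carboxylate atoms around a CD position."""
    cd = np.asarray(cd_position, float)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    perp = np.array([-d[1], d[0], 0.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    atoms = [
        Atom("CA", "C", cd - 3.0 * d),
        Atom("CB", "C", cd - 2.0 * d),
        Atom("CG", "C", cd - 1.5 * d),
        Atom("CD", "C", cd),
        Atom("OE1", "O", cd + 1.25 * (0.5 * d + 0.87 * perp)),
        Atom("OE2", "O", cd + 1.25 * (0.5 * d - 0.87 * perp)),
    ]
    return Residue(number=chain_resnum[1], name="GLU", atoms=atoms)


def make_leu(chain_resnum: tuple[str, int], cd1_position, direction=(1.0, 0.0, 0.0)):
    """Leucine with an explicit side-chain carbon cluster ending at CD1."""
    cd1 = np.asarray(cd1_position, float)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    atoms = [
        Atom("CA", "C", cd1 - 3.0 * d),
        Atom("CB", "C", cd1 - 2.0 * d),
        Atom("CG", "C", cd1 - 1.0 * d),
        Atom("CD1", "C", cd1),
        Atom("CD2", "C", cd1 - 1.0 * d + np.array([0.0, 1.2, 0.0])),
    ]
    return Residue(number=chain_resnum[1], name="LEU", atoms=atoms)


@pytest.fixture
def salt_bridge_pair_factory():
    """Build a two-chain model with an Arg NH1 ... Glu OE1 pair at a given
    nitrogen-oxygen distance (atoms placed on the x axis)."""

    def build(distance: float) -> StructureModel:
        arg = make_arg(("A", 8), np.zeros(3), direction=(1.0, 0.0, 0.0))
        nh1 = arg.atom("NH1").position
        glu = make_glu(("B", 37), nh1 + np.array([distance + 1.25 * 0.5, 0.0, 0.0]),
                       direction=(-1.0, 0.0, 0.0))
        # place OE1 exactly `distance` from NH1 along x
        oe1 = glu.atom("OE1")
        shift = nh1 + np.array([distance, 0.0, 0.0]) - oe1.position
        for a in glu.atoms:
            a.position = a.position + shift
        return StructureModel(
            identifier="salt_bridge_fixture",
            chains=[Chain("A", [arg]), Chain("B", [glu])],
        )

    return build


@pytest.fixture
def leu_contact_pair_factory():
    """Two Leu side chains on different chains with closest C-C at a given
    distance (CD1-CD1 along x)."""

    def build(distance: float) -> StructureModel:
        l1 = make_leu(("A", 4), np.zeros(3), direction=(1.0, 0.0, 0.0))
        l2 = make_leu(("B", 21), np.array([distance, 0.0, 0.0]), direction=(-1.0, 0.0, 0.0))
        return StructureModel(
            identifier="leu_fixture", chains=[Chain("A", [l1]), Chain("B", [l2])]
        )

    return build


# ---------------------------------------------------------------------------
# deposited accessions (optional user-supplied inputs)

def load_accession(stem: str):
    """Load a deposited structure/profile from data/accessions, or fail.

    The deposited coordinate sets and the scattering profile are inputs the
    package consumes; they are not redistributed with the repository. Place
    e.g. 8h8h.cif / 5b52.pdb / sasdup4.dat under data/accessions/ to run the
    reproduction tests.
    """
    for suffix in (".cif", ".cif.gz", ".pdb", ".pdb.gz", ".ent", ".dat"):
        path = ACCESSION_DIR / f"{stem}{suffix}"
        if path.exists():
            if suffix == ".dat":
                from oligomod.saxs import read_profile

                return read_profile(path)
            from oligomod.structio import read_structure

            return read_structure(path)
    pytest.fail(
        f"deposited input {stem!r} not found under {ACCESSION_DIR}; "
        "download it and place it there to run this reproduction test",
        pytrace=False,
    )
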
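"""Numeric lookup tables: van der Waals radii, electron counts, atomic volumes.

Radii are a Bondi-type set for the heavy elements found in proteins; they are
used both for solvent-accessible surface area and for steric-clash checks.
Displaced-solvent volumes (A^3) follow the standard values used in
excess-scattering calculations; bulk water electron density is 0.334 e/A^3.
"""

from __future__ import annotations

# Bondi van der Waals radii (A), heavy atoms only; hydrogens are never kept.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "H": 1.20,  # tabulated for completeness; structures are hydrogen-free
    "X": 1.70,  # beads / pseudo-atoms from the synthetic generator
}

# Electron counts per element (neutral atoms).
ELECTRON_COUNTS: dict[str, float] = {
    "H": 1.0,
    "C": 6.0,
    "N": 7.0,
    "O": 8.0,
    "S": 16.0,
    "P": 15.0,
    "SE": 34.0,
    "X": 1.0,  # unit-weight beads
}

# Displaced-solvent volumes (A^3) per heavy element, Fraser-type values.
DISPLACED_VOLUMES: dict[str, float] = {
    "H": 5.15,
    "C": 16.44,
    "N": 2.49,
    "O": 9.13,
    "S": 19.86,
    "P": 5.73,
    "SE": 19.86,
    "X": 0.0,
}

WATER_ELECTRON_DENSITY = 0.334  # e / A^3

# Side-chain atoms defining salt-bridge donors/acceptors.
BASIC_NITROGENS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
}
HISTIDINE_NITROGENS: dict[str, tuple[str, ...]] = {"HIS": ("ND1", "NE2")}
ACIDIC_OXYGENS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

# Residues whose side-chain carbons count as apolar contact atoms; glycine
# participates through its CA (it has no side chain).
HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"}
)
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
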
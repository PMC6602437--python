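"""Standard amino-acid chemistry tables.

Heavy-atom compositions of the 20 standard residues (PDB v3 atom naming),
one-letter codes, and side-chain topology hints used by the synthetic
structure generators.  The backbone OXT oxygen is accepted on any residue.
"""

from __future__ import annotations

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Side-chain heavy atoms per residue, in PDB convention order.
SIDE_CHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("CB", "CG1", "CG2"),
}

STANDARD_RESIDUES = tuple(sorted(SIDE_CHAIN_ATOMS))

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}


def residue_heavy_atoms(residue_name: str) -> tuple[str, ...]:
    """All heavy atoms of a standard residue (without OXT)."""
    return BACKBONE_ATOMS + SIDE_CHAIN_ATOMS[residue_name]


def element_of(atom_name: str) -> str:
    """Infer the element from a protein heavy-atom name (PDB convention)."""
    name = atom_name.strip()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


# Side-chain placement templates for the synthetic polypeptide generator:
# (atom_name, depth in bonds from CB, lateral slot in {-1, 0, 1}).
# Chemically naive by design — only naming, connectivity-consistent
# distances and reproducibility matter.
SIDE_CHAIN_TEMPLATES: dict[str, tuple[tuple[str, int, int], ...]] = {
    "ALA": (("CB", 0, 0),),
    "SER": (("CB", 0, 0), ("OG", 1, 0)),
    "CYS": (("CB", 0, 0), ("SG", 1, 0)),
    "THR": (("CB", 0, 0), ("OG1", 1, -1), ("CG2", 1, 1)),
    "VAL": (("CB", 0, 0), ("CG1", 1, -1), ("CG2", 1, 1)),
    "LEU": (("CB", 0, 0), ("CG", 1, 0), ("CD1", 2, -1), ("CD2", 2, 1)),
    "ILE": (("CB", 0, 0), ("CG1", 1, -1), ("CG2", 1, 1), ("CD1", 2, -1)),
    "MET": (("CB", 0, 0), ("CG", 1, 0), ("SD", 2, 0), ("CE", 3, 0)),
    "ASP": (("CB", 0, 0), ("CG", 1, 0), ("OD1", 2, -1), ("OD2", 2, 1)),
    "ASN": (("CB", 0, 0), ("CG", 1, 0), ("OD1", 2, -1), ("ND2", 2, 1)),
    "GLU": (("CB", 0, 0), ("CG", 1, 0), ("CD", 2, 0), ("OE1", 3, -1), ("OE2", 3, 1)),
    "GLN": (("CB", 0, 0), ("CG", 1, 0), ("CD", 2, 0), ("OE1", 3, -1), ("NE2", 3, 1)),
    "LYS": (("CB", 0, 0), ("CG", 1, 0), ("CD", 2, 0), ("CE", 3, 0), ("NZ", 4, 0)),
    "ARG": (("CB", 0, 0), ("CG", 1, 0), ("CD", 2, 0), ("NE", 3, 0), ("CZ", 4, 0),
            ("NH1", 5, -1), ("NH2", 5, 1)),
    "HIS": (("CB", 0, 0), ("CG", 1, 0), ("ND1", 2, -1), ("CD2", 2, 1),
            ("CE1", 3, -1), ("NE2", 3, 1)),
    "PHE": (("CB", 0, 0), ("CG", 1, 0), ("CD1", 2, -1), ("CD2", 2, 1),
            ("CE1", 3, -1), ("CE2", 3, 1), ("CZ", 4, 0)),
    "TYR": (("CB", 0, 0), ("CG", 1, 0), ("CD1", 2, -1), ("CD2", 2, 1),
            ("CE1", 3, -1), ("CE2", 3, 1), ("CZ", 4, 0), ("OH", 5, 0)),
    "TRP": (("CB", 0, 0), ("CG", 1, 0), ("CD1", 2, -1), ("CD2", 2, 1),
            ("NE1", 3, -1), ("CE2", 3, 0), ("CE3", 3, 1),
            ("CZ2", 4, 0), ("CZ3", 4, 1), ("CH2", 5, 1)),
    "GLY": (),
    "PRO": (("CB", 0, 0), ("CG", 1, -1), ("CD", 1, 1)),
}
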
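"""Hydrogen-bond chemistry dictionaries for protein and DNA residues.

Fixed lookup tables used by the contact detector: donor and acceptor heavy
atoms per residue type, groove-face assignment of base atoms, moiety
classification of nucleotide atoms, and the planar side-chain groups that are
eligible for intercalation into a base-stack cavity.

Hydroxyls (Ser/Thr/Tyr) and histidine ring nitrogens can act as either donor
or acceptor and are listed as ambivalent.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Residue-kind dictionaries
# ---------------------------------------------------------------------------

PROTEIN_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}

NUCLEOTIDE_RESIDUES = {
    "DA", "DT", "DG", "DC", "DU", "DI",
    "A", "U", "G", "C", "T", "I",
}

WATER_RESIDUES = {"HOH", "WAT", "DOD", "H2O"}

AA_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}

NUC_TO_ONE = {
    "DA": "A", "DT": "T", "DG": "G", "DC": "C", "DU": "U", "DI": "I",
    "A": "A", "T": "T", "G": "G", "C": "C", "U": "U", "I": "I",
}

#: One-letter base of a nucleotide residue name (duplicate of NUC_TO_ONE kept
#: separate so protein and nucleic lookups cannot be confused).
BASE_OF = dict(NUC_TO_ONE)

WATSON_CRICK = {"A": "T", "T": "A", "G": "C", "C": "G", "U": "A"}

# IUPAC nucleotide degeneracy codes (lower/upper handled by callers).
IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# ---------------------------------------------------------------------------
# Protein hydrogen-bond chemistry (heavy atoms only)
# ---------------------------------------------------------------------------

#: Side-chain donor atoms per residue.
PROTEIN_SC_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "TRP": {"NE1"},
}

#: Side-chain acceptor atoms per residue.
PROTEIN_SC_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "MET": set(),  # thioether: too weak, excluded
}

#: Side-chain atoms treated as both donor and acceptor.
PROTEIN_SC_AMBIVALENT = {
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
}

#: Main-chain polar atoms, identical for every residue type.
PROTEIN_MC_DONORS = {"N"}
PROTEIN_MC_ACCEPTORS = {"O", "OXT"}

#: Planar side-chain groups eligible for intercalation into the base stack.
PLANAR_GROUPS = {
    "ARG": ("NE", "CZ", "NH1", "NH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}

# ---------------------------------------------------------------------------
# DNA hydrogen-bond chemistry, per one-letter base
# ---------------------------------------------------------------------------

BASE_DONORS = {
    "A": {"N6"},
    "G": {"N1", "N2"},
    "C": {"N4"},
    "T": {"N3"},
}

BASE_ACCEPTORS = {
    "A": {"N7", "N1", "N3"},
    "G": {"O6", "N7", "N3"},
    "C": {"N3", "O2"},
    "T": {"O4", "O2"},
}

#: Groove exposure of base atoms: purine N7/O6/N6 face the major groove,
#: N3/O2/N2 the minor groove; Watson-Crick atoms face neither.
BASE_MAJOR_ATOMS = {
    "A": {"N7", "N6"},
    "G": {"N7", "O6"},
    "C": {"N4", "C5"},
    "T": {"O4", "C7", "C5M"},
}

BASE_MINOR_ATOMS = {
    "A": {"N3", "C2"},
    "G": {"N3", "N2"},
    "C": {"O2"},
    "T": {"O2"},
}

#: Watson-Crick pairing atom used for partner assignment and pairing checks.
PAIRING_ATOM = {"A": "N1", "G": "N1", "C": "N3", "T": "N3", "U": "N3", "I": "N1"}

#: Glycosidic nitrogen (base attachment point).
GLYCOSIDIC_ATOM = {"A": "N9", "G": "N9", "C": "N1", "T": "N1", "U": "N1", "I": "N9"}

#: Base ring/substituent atom names (union over bases) used for centroids,
#: plane fits and flip detection.  Everything that is neither backbone,
#: sugar nor phosphate is base.
SUGAR_ATOMS = {"C1'", "C2'", "C3'", "C4'", "C5'", "O4'", "O2'"}
PHOSPHATE_ATOMS = {"P", "OP1", "OP2", "OP3", "O5'", "O3'", "O1P", "O2P"}

#: Backbone acceptors available for non-specific contacts.
BACKBONE_ACCEPTORS = {"OP1", "OP2", "O1P", "O2P", "O3'", "O5'", "O4'"}


def base_atom_names(base: str) -> set[str]:
    """All heavy base atoms the reduced or full representation may carry."""
    names = {PAIRING_ATOM[base], GLYCOSIDIC_ATOM[base]}
    names |= BASE_DONORS.get(base, set())
    names |= BASE_ACCEPTORS.get(base, set())
    names |= BASE_MAJOR_ATOMS.get(base, set())
    names |= BASE_MINOR_ATOMS.get(base, set())
    return names


def is_base_atom(base: str, atom: str) -> bool:
    return atom not in SUGAR_ATOMS and atom not in PHOSPHATE_ATOMS


def moiety_of(atom: str) -> str:
    """Classify a nucleotide atom as base, sugar or phosphate."""
    if atom in PHOSPHATE_ATOMS:
        return "phosphate"
    if atom in SUGAR_ATOMS:
        return "sugar"
    return "base"


def groove_of(base: str, atom: str) -> str:
    """Groove face of a base atom: major, minor, or n/a for WC-face atoms."""
    if atom in BASE_MAJOR_ATOMS.get(base, ()):
        return "major"
    if atom in BASE_MINOR_ATOMS.get(base, ()):
        return "minor"
    return "n/a"


def protein_donor_atoms(resname: str) -> set[str]:
    out = set(PROTEIN_MC_DONORS)
    out |= PROTEIN_SC_DONORS.get(resname, set())
    out |= PROTEIN_SC_AMBIVALENT.get(resname, set())
    return out


def protein_acceptor_atoms(resname: str) -> set[str]:
    out = set(PROTEIN_MC_ACCEPTORS)
    out |= PROTEIN_SC_ACCEPTORS.get(resname, set())
    out |= PROTEIN_SC_AMBIVALENT.get(resname, set())
    return out


def dna_donor_atoms(base: str) -> set[str]:
    return set(BASE_DONORS.get(base, set()))


def dna_acceptor_atoms(base: str) -> set[str]:
    return set(BASE_ACCEPTORS.get(base, set())) | BACKBONE_ACCEPTORS
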
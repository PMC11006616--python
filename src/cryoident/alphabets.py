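"""Residue alphabets shared across the package.

Amino acids use the 20 canonical one-letter codes in alphabetical order;
nucleotides are the four ribonucleotides. Index order here fixes the layout
of every identity-probability vector and profile-HMM emission row.
"""

from __future__ import annotations

AMINO_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDE_LETTERS = "ACGU"

AMINO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
AMINO_ONE = {v: k for k, v in AMINO_THREE.items()}

UNKNOWN = "X"


def letters(polymer: str) -> str:
    """Alphabet string for a polymer class ('amino' or 'nucleotide')."""
    if polymer == "amino":
        return AMINO_LETTERS
    if polymer == "nucleotide":
        return NUCLEOTIDE_LETTERS
    raise ValueError(f"unknown polymer class: {polymer!r}")


def residue_name(letter: str, polymer: str) -> str:
    """Three-letter (amino) or CCD (nucleotide) residue name for a code."""
    if letter == UNKNOWN:
        return "UNK"
    if polymer == "amino":
        return AMINO_THREE[letter]
    return letter


def one_letter(name: str, polymer: str) -> str:
    if name == "UNK":
        return UNKNOWN
    if polymer == "amino":
        return AMINO_ONE.get(name, UNKNOWN)
    return name if name in NUCLEOTIDE_LETTERS else UNKNOWN
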
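"""Shared residue and subsite-position vocabulary.

Positions follow Schechter–Berger nomenclature for a dipeptidyl peptidase:
the peptide's first two residues occupy P2 and P1, cleavage occurs between
P1 and P1', so the N-terminal hexamer covers P2..P4'.
"""

from __future__ import annotations

#: The 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

AA_SET = frozenset(AMINO_ACIDS)

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Ambiguity/nonstandard letters that may appear in databases but are
#: outside the model's categorical space.
NONSTANDARD_LETTERS = frozenset("BJOUXZ")

#: Subsite positions covered by the N-terminal hexamer, in peptide order.
POSITIONS: tuple[str, ...] = ("P2", "P1", "P1'", "P2'", "P3'", "P4'")

#: Map position label -> 0-based index into the hexamer.
POSITION_INDEX = {pos: i for i, pos in enumerate(POSITIONS)}

#: Residues after which trypsin cleaves.
TRYPTIC_RESIDUES = frozenset("KR")


def is_standard(sequence: str) -> bool:
    """True if every letter is one of the 20 standard residues."""
    return all(c in AA_SET for c in sequence)
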
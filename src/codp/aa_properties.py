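"""Amino-acid property tables used by the structural feature of the predictor.

The volume change of a substitution is proxied by the change in the number of
non-hydrogen (heavy) side-chain atoms between the wild-type and mutant residue
types.  Glycine has none; tryptophan, with 10, has the most.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

__all__ = [
    "AminoAcid",
    "AMINO_ACIDS",
    "ONE_TO_THREE",
    "THREE_TO_ONE",
    "SIDE_CHAIN_HEAVY_ATOMS",
    "UnknownResidueError",
    "side_chain_heavy_atom_count",
    "delta_heavy_atoms",
    "property_table_tsv",
]


class UnknownResidueError(ValueError):
    """Raised for residue codes outside the 20 canonical amino acids."""


@dataclass(frozen=True)
class AminoAcid:
    one_letter: str
    three_letter: str
    side_chain_heavy_atoms: int


# Heavy-atom counts follow the standard residue topologies (PDB chemical
# component dictionary), side chain = everything beyond the backbone
# N/CA/C/O (CB included).
AMINO_ACIDS: tuple[AminoAcid, ...] = (
    AminoAcid("A", "ALA", 1),
    AminoAcid("R", "ARG", 7),
    AminoAcid("N", "ASN", 4),
    AminoAcid("D", "ASP", 4),
    AminoAcid("C", "CYS", 2),
    AminoAcid("Q", "GLN", 5),
    AminoAcid("E", "GLU", 5),
    AminoAcid("G", "GLY", 0),
    AminoAcid("H", "HIS", 6),
    AminoAcid("I", "ILE", 4),
    AminoAcid("L", "LEU", 4),
    AminoAcid("K", "LYS", 5),
    AminoAcid("M", "MET", 4),
    AminoAcid("F", "PHE", 7),
    AminoAcid("P", "PRO", 3),
    AminoAcid("S", "SER", 2),
    AminoAcid("T", "THR", 3),
    AminoAcid("W", "TRP", 10),
    AminoAcid("Y", "TYR", 8),
    AminoAcid("V", "VAL", 3),
)

ONE_TO_THREE: dict[str, str] = {aa.one_letter: aa.three_letter for aa in AMINO_ACIDS}
THREE_TO_ONE: dict[str, str] = {aa.three_letter: aa.one_letter for aa in AMINO_ACIDS}
SIDE_CHAIN_HEAVY_ATOMS: dict[str, int] = {
    aa.one_letter: aa.side_chain_heavy_atoms for aa in AMINO_ACIDS
}


def _check_code(aa: str) -> str:
    if not isinstance(aa, str):
        raise UnknownResidueError(f"residue code must be a string, got {aa!r}")
    code = aa.upper()
    if code not in SIDE_CHAIN_HEAVY_ATOMS:
        raise UnknownResidueError(
            f"{aa!r} is not one of the 20 canonical one-letter amino-acid codes"
        )
    return code


def side_chain_heavy_atom_count(aa: str) -> int:
    """Number of non-hydrogen side-chain atoms of a canonical residue type.

    Ambiguous or non-standard codes (B, Z, X, U, ...) raise
    :class:`UnknownResidueError` — the predictor is only defined over the 20
    canonical types.
    """
    return SIDE_CHAIN_HEAVY_ATOMS[_check_code(aa)]


def delta_heavy_atoms(wt: str, mut: str) -> int:
    """Absolute change in side-chain heavy-atom count for a substitution.

    Symmetric in its arguments and bounded by 10 (glycine <-> tryptophan).
    """
    return abs(side_chain_heavy_atom_count(mut) - side_chain_heavy_atom_count(wt))


def property_table_tsv() -> str:
    """The property table as TSV text (one_letter, three_letter, heavy_atoms)."""
    buf = io.StringIO()
    buf.write("one_letter\tthree_letter\theavy_atoms\n")
    for aa in AMINO_ACIDS:
        buf.write(f"{aa.one_letter}\t{aa.three_letter}\t{aa.side_chain_heavy_atoms}\n")
    return buf.getvalue()
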
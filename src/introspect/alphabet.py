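"""Residue alphabet shared by every module.

The 20 standard residues are kept in the fixed order ``ACDEFGHIKLMNPQRSTVWY``;
every matrix in the package (PSSM, frequency profile, cluster counts) uses
that column order. Isoleucine and leucine are distinct throughout.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
N_RESIDUES: int = 20

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Ambiguity / non-standard codes tolerated in protein sequences but never in
#: peptides ('*' is additionally allowed as a trailing stop in FASTA entries).
AMBIGUOUS_CODES: frozenset[str] = frozenset("BJOUXZ")

_STANDARD_SET = frozenset(AMINO_ACIDS)

# uint8 lookup: byte code -> residue index, 255 for anything non-standard
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _aa, _i in AA_INDEX.items():
    _CODE_LUT[ord(_aa)] = _i


def is_standard_peptide(seq: str) -> bool:
    """True iff *seq* is non-empty and uses only the 20 standard residues."""
    return bool(seq) and _STANDARD_SET.issuperset(seq)


def encode_peptide(seq: str) -> np.ndarray:
    """Encode a peptide as residue indices (uint8).

    Raises
    ------
    ValueError
        If the sequence contains a character outside the 20-residue alphabet.
    """
    codes = _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.size == 0 or (codes == 255).any():
        bad = sorted(set(seq) - _STANDARD_SET)
        raise ValueError(f"peptide {seq!r} contains non-standard residues {bad}")
    return codes


def encode_peptides(seqs: list[str]) -> np.ndarray:
    """Encode equal-length peptides as an (n, L) uint8 matrix."""
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    codes = _CODE_LUT[arr].reshape(len(seqs), -1)
    if (codes == 255).any():
        rows = np.unique(np.nonzero(codes == 255)[0])
        raise ValueError(f"non-standard residues in peptides at rows {rows[:5].tolist()}")
    return codes


def encode_protein(seq: str) -> np.ndarray:
    """Encode a protein sequence; ambiguity codes map to 255 (to be masked)."""
    return _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
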
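"""The 20-letter amino-acid alphabet and peptide encoding helpers.

Every matrix in this package (PWMs, count matrices, background vectors)
is indexed by the canonical one-letter codes in alphabetical order.
"""

from __future__ import annotations

import numpy as np

#: The 20 canonical residues, alphabetical. This ordering is global.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

N_AA: int = 20

# Approximate human-proteome amino-acid frequencies (UniProt/Swiss-Prot
# composition statistics, renormalized over the 20 canonical residues).
_HUMAN_FREQS = {
    "A": 0.083, "C": 0.014, "D": 0.055, "E": 0.067, "F": 0.039,
    "G": 0.071, "H": 0.023, "I": 0.059, "K": 0.058, "L": 0.097,
    "M": 0.024, "N": 0.041, "P": 0.047, "Q": 0.039, "R": 0.055,
    "S": 0.066, "T": 0.054, "W": 0.011, "Y": 0.029, "V": 0.069,
}

HUMAN_PROTEOME_FREQS: np.ndarray = np.array(
    [_HUMAN_FREQS[a] for a in AMINO_ACIDS], dtype=float
)
HUMAN_PROTEOME_FREQS /= HUMAN_PROTEOME_FREQS.sum()


def is_canonical(sequence: str) -> bool:
    """True if every character is one of the 20 canonical residues."""
    return all(c in AA_INDEX for c in sequence)


def encode_peptides(peptides: list[str]) -> np.ndarray:
    """Encode equal-length peptides as an (n, L) integer array.

    Raises ValueError on mixed lengths or non-canonical residues.
    """
    if not peptides:
        raise ValueError("empty peptide list")
    L = len(peptides[0])
    out = np.empty((len(peptides), L), dtype=np.int64)
    for r, pep in enumerate(peptides):
        if len(pep) != L:
            raise ValueError(f"mixed peptide lengths: {len(pep)} vs {L}")
        try:
            out[r] = [AA_INDEX[c] for c in pep]
        except KeyError as exc:
            raise ValueError(f"non-canonical residue in {pep!r}") from exc
    return out


def decode_peptide(codes: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[int(c)] for c in codes)


def one_hot(encoded: np.ndarray) -> np.ndarray:
    """(n, L) integer codes -> (n, L*20) flat one-hot float matrix."""
    n, L = encoded.shape
    flat = np.zeros((n, L * N_AA), dtype=float)
    cols = encoded + np.arange(L) * N_AA
    flat[np.arange(n)[:, None], cols] = 1.0
    return flat
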
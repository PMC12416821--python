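"""Codon/translation helpers shared by the simulator and the AA-distance code.

Bases are 2-bit coded A=0, C=1, G=2, T=3 (see :mod:`digs._align`). Translation
uses NCBI table 11 (bacterial); internal codon->amino-acid assignments are
identical to the standard code.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
_TABLE = CodonTable.unambiguous_dna_by_id[11]

#: codon index (base-4 of its 2-bit codes) -> amino-acid letter, '*' for stops
CODON_TO_AA = np.empty(64, dtype="<U1")
AA_TO_CODONS: dict[str, list[int]] = {}
STOP_CODON_INDICES: list[int] = []
for _i in range(64):
    codon = BASES[_i >> 4] + BASES[(_i >> 2) & 3] + BASES[_i & 3]
    if codon in _TABLE.stop_codons:
        CODON_TO_AA[_i] = "*"
        STOP_CODON_INDICES.append(_i)
    else:
        aa = _TABLE.forward_table[codon]
        CODON_TO_AA[_i] = aa
        AA_TO_CODONS.setdefault(aa, []).append(_i)

ATG = np.array([0, 3, 2], dtype=np.uint8)  # the canonical start codon


def codon_index(codes: np.ndarray) -> int:
    """Base-4 index of a 3-base code array."""
    return int(codes[0]) * 16 + int(codes[1]) * 4 + int(codes[2])


def codon_codes(index: int) -> np.ndarray:
    return np.array([index >> 4, (index >> 2) & 3, index & 3], dtype=np.uint8)


def is_stop(codes: np.ndarray) -> bool:
    return CODON_TO_AA[codon_index(codes)] == "*"


def codon_hamming(i: int, j: int) -> int:
    """Hamming distance between two codons given by their base-4 indices."""
    return sum(
        1 for shift in (4, 2, 0) if ((i >> shift) & 3) != ((j >> shift) & 3)
    )


def translate_codes(codes: np.ndarray) -> str:
    """Translate a frame-aligned 2-bit code array; trailing partial codon ignored."""
    n = (codes.size // 3) * 3
    c = codes[:n].reshape(-1, 3).astype(np.int64)
    idx = c[:, 0] * 16 + c[:, 1] * 4 + c[:, 2]
    return "".join(CODON_TO_AA[idx])


def codes_to_str(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def str_to_codes(seq: str) -> np.ndarray:
    from ._align import encode_sequence

    codes = encode_sequence(seq)
    if (codes == 4).any():
        raise ValueError("sequence contains non-ACGT characters")
    return codes
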
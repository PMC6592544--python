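"""Low-level sequence utilities: translation, alphabets, one-mismatch neighborhoods.

The amino-acid neighborhood used throughout the package is substitution-only:
two CDR3s are neighbors iff they have the same length and Hamming distance <= 1.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

NUCLEOTIDES = "ACGT"

#: The 20 canonical amino acids, alphabetical one-letter codes.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

STOP = "*"

# Standard genetic code, codon -> one-letter amino acid ('*' for stop).
_BASES = NUCLEOTIDES
_AA64 = (
    "KNKNTTTTRSRSIIMIQHQHPPPPRRRRLLLL"
    "EDEDAAAAGGGGVVVV*Y*YSSSS*CWCLFLF"
)
# Order above follows index = 16*b1 + 4*b2 + b3 with A=0,C=1,G=2,T=3.
CODON_TABLE = {}
for i1, b1 in enumerate(_BASES):
    for i2, b2 in enumerate(_BASES):
        for i3, b3 in enumerate(_BASES):
            CODON_TABLE[b1 + b2 + b3] = _AA64[16 * i1 + 4 * i2 + i3]

# Reverse table: amino acid -> tuple of codons.
CODONS_FOR_AA: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CODON_TABLE.items():
    CODONS_FOR_AA.setdefault(_aa, ())
    CODONS_FOR_AA[_aa] = CODONS_FOR_AA[_aa] + (_codon,)

# uint8 lookup tables for vectorized translation.
_NT_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _NT_CODE[ord(_b)] = _i
    _NT_CODE[ord(_b.lower())] = _i
_AA_BYTES = np.frombuffer(_AA64.encode(), dtype=np.uint8)


def translate(nt: str) -> str:
    """Translate an in-frame nucleotide string with the standard code.

    Raises ``ValueError`` if the length is not a multiple of 3 or a
    non-ACGT character is present.
    """
    if len(nt) % 3 != 0:
        raise ValueError(f"length {len(nt)} is not a multiple of 3")
    try:
        return "".join(CODON_TABLE[nt[i : i + 3].upper()] for i in range(0, len(nt), 3))
    except KeyError as exc:  # non-ACGT character
        raise ValueError(f"non-ACGT codon in {nt!r}") from exc


def translate_matrix(nt_codes: np.ndarray) -> np.ndarray:
    """Translate a (n, 3*L) uint8 matrix of nucleotide codes (A=0..T=3).

    Returns a (n, L) uint8 matrix of amino-acid ASCII bytes ('*' for stops).
    """
    n, w = nt_codes.shape
    if w % 3 != 0:
        raise ValueError("width not a multiple of 3")
    cod = nt_codes.reshape(n, w // 3, 3).astype(np.int32)
    idx = 16 * cod[:, :, 0] + 4 * cod[:, :, 1] + cod[:, :, 2]
    return _AA_BYTES[idx]


def encode_nt(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes A=0, C=1, G=2, T=3."""
    codes = _NT_CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError(f"non-ACGT character in {seq!r}")
    return codes


def is_canonical_aa(seq: str) -> bool:
    """True iff every character is one of the 20 canonical amino acids."""
    return bool(seq) and all(c in AA_INDEX for c in seq)


def one_mismatch_variants(sigma: str) -> Iterator[str]:
    """Yield the 19*len(sigma) distinct single-substitution variants of sigma."""
    for i, orig in enumerate(sigma):
        for a in AA_ALPHABET:
            if a != orig:
                yield sigma[:i] + a + sigma[i + 1 :]


def neighborhood(sigma: str) -> Iterator[str]:
    """Yield sigma followed by all of its single-substitution variants.

    The neighborhood contains 1 + 19*len(sigma) sequences; it is
    length-preserving (indels are not neighbors).
    """
    yield sigma
    yield from one_mismatch_variants(sigma)


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return sum(x != y for x, y in zip(a, b))


def is_neighbor(a: str, b: str) -> bool:
    """True iff a and b are same-length with at most one mismatch."""
    return len(a) == len(b) and hamming(a, b) <= 1
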
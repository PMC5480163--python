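"""Small DNA-string utilities used throughout the package.

Sequences are plain upper-case ``str`` over {A,C,G,T,N}; coordinates are
0-based half-open everywhere internally.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(n: int, rng: np.random.Generator) -> str:
    """i.i.d. uniform DNA string of length ``n``."""
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=n)])


def encode(seq: str) -> np.ndarray:
    """Encode A,C,G,T -> 0..3 and anything else -> 4, as uint8."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for base, code in _BASE_TO_CODE.items():
        out[arr == ord(base)] = code
    return out


def decode(codes: np.ndarray) -> str:
    lut = np.array(list(BASES + "N"))
    return "".join(lut[codes])


def canonical_rotation(seq: str) -> str:
    """Lexicographically minimal rotation of a circular sequence."""
    if not seq:
        return seq
    doubled = seq + seq
    best = min(doubled[i : i + len(seq)] for i in range(len(seq)))
    return best


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings; N never matches."""
    if len(a) != len(b):
        raise ValueError("hamming requires equal lengths")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")
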
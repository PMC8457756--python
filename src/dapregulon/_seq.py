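"""Low-level DNA sequence helpers shared across modules.

Sequences are strings over {A,C,G,T,N}; the integer encoding maps
A,C,G,T -> 0..3 and N -> 4.  All coordinates are 0-based half-open.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
N_CODE = 4

_ENCODE = np.full(256, N_CODE, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# complement in integer space; N maps to N
COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.int8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to int8 codes (A=0,C=1,G=2,T=3,N=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    alphabet = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return alphabet[np.asarray(codes, dtype=np.int64)].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complementary)."""
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return COMP_CODE[codes][::-1]


def clean_sequence(seq: str) -> tuple[str, int]:
    """Uppercase and map non-ACGTN characters to N.

    Returns the cleaned string and the number of characters replaced by N
    (not counting pre-existing N).
    """
    up = seq.upper()
    codes = encode(up)
    n_before = up.count("N")
    cleaned = decode(codes)
    n_after = cleaned.count("N")
    return cleaned, n_after - n_before
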
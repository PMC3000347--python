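"""Low-level sequence helpers shared across modules.

Sequences are plain uppercase ACGTN strings; hot loops work on uint8
numpy views of the same bytes (b"A" == 65 etc.), so conversion between
the two representations is free of copies where possible.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: uint8 codes for A,C,G,T in ASCII.
A, C, G, T = 65, 67, 71, 84
BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    """View a DNA string as a uint8 array of ASCII codes (no copy)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def random_dna(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random DNA as a uint8 ASCII array."""
    return _BASE_ARR[rng.integers(0, 4, size=n)]


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Number of mismatching positions between equal-length uint8 arrays."""
    return int(np.count_nonzero(a != b))


def encode_2bit(arr: np.ndarray) -> np.ndarray:
    """Map ASCII ACGT codes to 0..3; other bytes (N) map to 4."""
    out = np.full(arr.shape, 4, dtype=np.int64)
    out[arr == A] = 0
    out[arr == C] = 1
    out[arr == G] = 2
    out[arr == T] = 3
    return out
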
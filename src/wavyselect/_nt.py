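"""Internal nucleotide encoding helpers shared across modules.

Bases map A,C,G,T -> 0..3; anything else (N, separators) -> 4. Encoding is
byte-table based so whole sequences encode in one vectorised pass.
"""

from __future__ import annotations

import numpy as np

_ENCODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _ENCODE[b] = i
    _ENCODE[b + 32] = i  # lowercase

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def encode(seq: str) -> np.ndarray:
    """Sequence -> uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    """uint8 codes in 0..3 -> sequence string."""
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def splitmix64(x: np.ndarray) -> np.ndarray:
    """Invertible 64-bit mix (splitmix64 finalizer), vectorised on uint64."""
    x = x.astype(np.uint64, copy=True)
    with np.errstate(over="ignore"):
        x += np.uint64(0x9E3779B97F4A7C15)
        x ^= x >> np.uint64(30)
        x *= np.uint64(0xBF58476D1CE4E5B9)
        x ^= x >> np.uint64(27)
        x *= np.uint64(0x94D049BB133111EB)
        x ^= x >> np.uint64(31)
    return x
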
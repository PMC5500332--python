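"""Nucleotide encoding helpers shared by the simulator and read processing.

Sequences are held as numpy uint8 arrays with A=0, C=1, G=2, T=3, N=4.
Vectorized batches (2-D arrays, one read per row) keep the per-read Python
overhead out of the hot paths.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGTN"
A, C, G, T, N = range(5)

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

# complement: A<->T, C<->G, N->N
_COMPLEMENT = np.array([T, G, C, A, N], dtype=np.uint8)

_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sorted({ch for ch in seq if ch.upper() not in BASES})
        raise ValueError(f"sequence contains non-nucleotide characters: {bad}")
    return arr


def decode(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode("ascii")


def revcomp(arr: np.ndarray) -> np.ndarray:
    """Reverse complement of an encoded sequence (1-D) or batch (2-D, per row)."""
    return _COMPLEMENT[arr][..., ::-1]


def revcomp_str(seq: str) -> str:
    return decode(revcomp(encode(seq)))
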
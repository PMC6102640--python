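"""Low-level DNA sequence encoding helpers.

Sequences are held as ``uint8`` arrays with A=0, C=1, G=2, T=3, N=4.
All hot loops in the package operate on this encoding; strings appear
only at file-format boundaries.
"""

from __future__ import annotations

import numpy as np

BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _ENCODE[_c] = _i
    _ENCODE[_c + 32] = _i  # lower case

# complement of codes 0..4 (N -> N)
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a DNA string into uint8 codes (unknown letters become N)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENCODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return BASES[codes].tobytes().decode("ascii")


def revcomp(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling k-mer integer codes of a 1-D encoded sequence.

    Returns ``(kmers, valid)`` where ``kmers[i]`` is the base-4 code of the
    k-mer starting at i and ``valid[i]`` is False when the window contains N.
    """
    n = codes.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    out = np.zeros(n, dtype=np.uint64)
    for i in range(k):
        out <<= np.uint64(2)
        out |= (codes[i : i + n] & 3).astype(np.uint64)
    # N-window detection via rolling max
    is_n = (codes == 4).astype(np.uint8)
    if is_n.any():
        bad = np.convolve(is_n, np.ones(k, dtype=np.uint8), mode="valid") > 0
        valid = ~bad
    else:
        valid = np.ones(n, dtype=bool)
    return out, valid


def kmer_codes_2d(reads: np.ndarray, k: int, stride: int = 1) -> np.ndarray:
    """k-mer codes at every ``stride``-th start position of each read row.

    No N handling; callers screen N-containing reads separately.  A
    stride > 1 trades sensitivity for speed: a query sharing an exact
    run of ``k + stride - 1`` bases with the reference is still
    guaranteed to produce a hit.
    """
    n_pos = reads.shape[1] - k + 1
    dtype = np.uint32 if 2 * k <= 32 else np.uint64
    if n_pos <= 0:
        return np.zeros((reads.shape[0], 0), dtype=dtype)
    starts = np.arange(0, n_pos, stride)
    wide = reads.astype(dtype)
    out = np.zeros((reads.shape[0], starts.shape[0]), dtype=dtype)
    for i in range(k):
        out <<= dtype(2)
        out |= wide[:, starts + i] & dtype(3)
    return out
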
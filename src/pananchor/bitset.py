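"""Packed bit-vector utilities.

Tag presence/absence patterns and biallelic SNP genotypes are both binary
vectors over the same ordered taxa list, so they are stored packed 8 taxa per
byte.  The association scan then reduces to bitwise AND plus popcount, which
is what makes scanning millions of tag x SNP pairs tractable.

Bit order follows :func:`numpy.packbits` (big-endian within a byte); trailing
pad bits in the last byte are always zero, an invariant every constructor here
maintains so popcounts never need masking.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "pack",
    "unpack",
    "popcount",
    "intersect_count",
    "intersect_count_many",
    "n_bytes",
]


def n_bytes(n_bits: int) -> int:
    """Number of bytes needed to hold ``n_bits`` packed bits."""
    return (n_bits + 7) // 8


def pack(bits) -> np.ndarray:
    """Pack a 0/1 (or boolean) vector into a uint8 bitset.

    Pad bits beyond the vector length are zero.
    """
    arr = np.asarray(bits)
    if arr.ndim != 1:
        raise ValueError("pack expects a 1-D vector")
    return np.packbits(arr.astype(bool))


def unpack(packed: np.ndarray, n_bits: int) -> np.ndarray:
    """Inverse of :func:`pack`; returns a uint8 0/1 vector of length ``n_bits``."""
    return np.unpackbits(packed, count=n_bits)


def popcount(packed: np.ndarray) -> int:
    """Number of set bits in a packed vector."""
    return int(np.bitwise_count(packed).sum())


def intersect_count(a: np.ndarray, b: np.ndarray) -> int:
    """popcount(a AND b) for two packed vectors of equal byte length."""
    if a.shape != b.shape:
        raise ValueError(f"bitset length mismatch: {a.shape} vs {b.shape}")
    return int(np.bitwise_count(a & b).sum())


def intersect_count_many(matrix: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """popcount(row AND vec) for every row of a packed (n, n_bytes) matrix.

    The workhorse of the association scan: one call scores one tag against
    every SNP's call mask or minor-allele vector.
    """
    if matrix.ndim != 2 or matrix.shape[1] != vec.shape[0]:
        raise ValueError("matrix/vector byte-length mismatch")
    return np.bitwise_count(matrix & vec[None, :]).sum(axis=1, dtype=np.int64)
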
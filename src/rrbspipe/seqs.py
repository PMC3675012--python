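"""Low-level DNA sequence primitives shared by the simulator and the aligner.

Sequences are handled as ``uint8`` numpy arrays with the encoding
A=0, C=1, G=2, T=3, N=4.  All functions accept 1-D arrays (a single
sequence) or 2-D arrays (a batch of equal-length reads).
"""

from __future__ import annotations

import numpy as np

A, C, G, T, N = 0, 1, 2, 3, 4

_ENC = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i  # lowercase
_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)
_COMP = np.array([T, G, C, A, N], dtype=np.uint8)


def encode(seq: str | bytes) -> np.ndarray:
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENC[np.frombuffer(seq, dtype=np.uint8)].copy()


def decode(arr: np.ndarray) -> str:
    return _DEC[arr].tobytes().decode("ascii")


def complement(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr]


def revcomp(arr: np.ndarray) -> np.ndarray:
    """Reverse complement along the last axis (works on read batches)."""
    return _COMP[arr][..., ::-1]


def c2t(arr: np.ndarray) -> np.ndarray:
    out = arr.copy()
    out[out == C] = T
    return out


def g2a(arr: np.ndarray) -> np.ndarray:
    out = arr.copy()
    out[out == G] = A
    return out


class KmerIndex:
    """Exact k-mer lookup over one long encoded sequence.

    Positions whose window contains an N are not indexed.  Lookup is a
    binary search over hash-sorted positions, fully vectorised.
    """

    def __init__(self, seq: np.ndarray, k: int = 16):
        if k < 1 or k > 31:
            raise ValueError("k must be in [1, 31]")
        self.k = k
        L = len(seq)
        n_win = max(L - k + 1, 0)
        if n_win == 0:
            self.hashes = np.empty(0, dtype=np.uint64)
            self.positions = np.empty(0, dtype=np.int64)
            return
        h = np.zeros(n_win, dtype=np.uint64)
        for j in range(k):
            h += seq[j : j + n_win].astype(np.uint64) << np.uint64(2 * j)
        # windows containing N: running count of N positions
        is_n = (seq >= N).astype(np.int32)
        cs = np.concatenate([[0], np.cumsum(is_n)])
        valid = (cs[k:] - cs[:-k]) == 0
        pos = np.nonzero(valid)[0]
        h = h[valid]
        order = np.argsort(h, kind="stable")
        self.hashes = h[order]
        self.positions = pos[order].astype(np.int64)

    def hash_queries(self, mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Hash the first k columns of a (n, >=k) batch.

        Returns (hashes, valid) where invalid rows contain an N in the seed.
        """
        sub = mat[:, : self.k]
        mult = (np.uint64(4) ** np.arange(self.k, dtype=np.uint64))
        valid = (sub < N).all(axis=1)
        h = (sub.astype(np.uint64) * mult).sum(axis=1)
        return h, valid

    def lookup(self, qhashes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (lo, hi) index ranges into ``self.positions`` per query."""
        lo = np.searchsorted(self.hashes, qhashes, side="left")
        hi = np.searchsorted(self.hashes, qhashes, side="right")
        return lo, hi


def expand_ranges(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flatten per-query [lo, hi) ranges into (owner_index, flat_index) pairs."""
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    owners = np.repeat(np.arange(len(lo), dtype=np.int64), counts)
    # flat index: lo[owner] + offset within its range
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    offsets = np.arange(total, dtype=np.int64) - np.repeat(starts, counts)
    flat = np.repeat(lo.astype(np.int64), counts) + offsets
    return owners, flat
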
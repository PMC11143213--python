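"""Vectorized k-mer encoding shared by the feature extractor and simulator.

Bases are 2-bit encoded (A=0, C=1, G=2, T=3); a k-mer is the integer whose
base-4 digits are the codes read 5'->3', so any k <= 31 fits in int64.
Windows containing N are invalid and dropped.  The canonical form of a
k-mer is the lexicographic minimum of itself and its reverse complement.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """2-bit codes for a DNA string; N (or any non-ACGT) becomes -1."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` for all-valid codes."""
    return _BASES[codes].tobytes().decode("ascii")


def _window_values(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(values, valid) for every length-k window of a code array."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    vals = np.zeros(n, dtype=np.int64)
    c64 = codes.astype(np.int64)
    for t in range(k):
        vals += np.where(c64[t : t + n] >= 0, c64[t : t + n], 0) << (2 * (k - 1 - t))
    bad = np.concatenate(([0], np.cumsum((codes < 0).astype(np.int64))))
    valid = (bad[k:] - bad[:-k]) == 0
    return vals, valid


def kmer_values(seq: str, k: int, canonical: bool = True) -> np.ndarray:
    """Integer values of the valid k-mer windows of ``seq``, in order.

    With ``canonical=True`` (default) each window is collapsed with its
    reverse complement; the result is then invariant to reverse
    complementing ``seq``.
    """
    codes = encode(seq)
    fwd, valid = _window_values(codes, k)
    if not canonical:
        return fwd[valid]
    # reverse complement of window i of seq == window (n-1-i) of revcomp(seq)
    rc_codes = np.where(codes >= 0, 3 - codes, -1)[::-1]
    rc, _ = _window_values(rc_codes, k)
    n = fwd.size
    rc_aligned = rc[::-1] if n else rc
    return np.minimum(fwd, rc_aligned)[valid]


def _revcomp_value(value: int, k: int) -> int:
    out = 0
    for _ in range(k):
        out = (out << 2) | (3 - (value & 3))
        value >>= 2
    return out


def canonical_tetramer_classes() -> np.ndarray:
    """Lookup table mapping each of the 256 4-mer values to its canonical
    (reverse-complement-collapsed) class index; there are 136 classes."""
    canon = np.array([min(v, _revcomp_value(v, 4)) for v in range(256)], dtype=np.int64)
    classes, index = np.unique(canon, return_inverse=True)
    assert classes.size == 136
    return index


TETRAMER_CLASS = canonical_tetramer_classes()
N_TETRAMER_CLASSES = int(TETRAMER_CLASS.max()) + 1


class KmerCounter:
    """Exact streaming counter for canonical k-mer occurrences.

    Codes are buffered and periodically compressed with ``np.unique`` so
    memory stays bounded by ``merge_every`` pending codes regardless of
    input size; counts are exact regardless of when merges happen.
    """

    def __init__(self, k: int, canonical: bool = True, merge_every: int = 4_000_000):
        self.k = k
        self.canonical = canonical
        self.merge_every = int(merge_every)
        self._pending: list[np.ndarray] = []
        self._pending_size = 0
        self._keys = np.empty(0, dtype=np.int64)
        self._counts = np.empty(0, dtype=np.int64)

    def add(self, seq: str) -> None:
        vals = kmer_values(seq, self.k, self.canonical)
        if vals.size:
            self._pending.append(vals)
            self._pending_size += vals.size
            if self._pending_size >= self.merge_every:
                self._merge()

    def _merge(self) -> None:
        if not self._pending:
            return
        chunk_keys, chunk_counts = np.unique(np.concatenate(self._pending), return_counts=True)
        self._pending = []
        self._pending_size = 0
        if self._keys.size == 0:
            self._keys, self._counts = chunk_keys, chunk_counts
            return
        merged = np.concatenate([self._keys, chunk_keys])
        weights = np.concatenate([self._counts, chunk_counts])
        keys, inverse = np.unique(merged, return_inverse=True)
        counts = np.zeros(keys.size, dtype=np.int64)
        np.add.at(counts, inverse, weights)
        self._keys, self._counts = keys, counts

    def finalize(self) -> tuple[np.ndarray, np.ndarray]:
        self._merge()
        return self._keys, self._counts
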
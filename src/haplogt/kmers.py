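"""Canonical k-mers, 64-bit hashing and (w,k)-minimizer extraction.

k-mers are 2-bit packed (A=0, C=1, G=2, T=3); the canonical form of a k-mer
is the numeric minimum of the packed forward and reverse-complement values,
which coincides with the lexicographic minimum under this encoding.  Hashes
come from an invertible splitmix64-style finalizer, so distinct k-mers map
to distinct 64-bit values.  Positions whose k-mer contains N are skipped.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_U64 = np.uint64
_MASK64 = _U64(0xFFFFFFFFFFFFFFFF)


def encode(seq: str) -> np.ndarray:
    """2-bit codes per base; 255 marks N/invalid characters."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def mix64(x: np.ndarray | int):
    """Invertible 64-bit finalizer (splitmix64)."""
    with np.errstate(over="ignore"):
        z = np.asarray(x, dtype=np.uint64)
        z = (z + _U64(0x9E3779B97F4A7C15)) & _MASK64
        z = (z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9) & _MASK64
        z = (z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB) & _MASK64
        z = z ^ (z >> _U64(31))
    return z


def _packed_kmers(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(canonical packed values, validity mask) for every k-mer start."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = ~np.any(win == 255, axis=1)
    w64 = np.where(win == 255, 0, win).astype(np.uint64)
    fwd_pow = (_U64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    rev_pow = (_U64(4) ** np.arange(k, dtype=np.uint64))
    with np.errstate(over="ignore"):
        fwd = (w64 * fwd_pow).sum(axis=1, dtype=np.uint64)
        rev = ((_U64(3) - w64) * rev_pow).sum(axis=1, dtype=np.uint64)
    canon = np.minimum(fwd, rev)
    return canon, valid


def canonical_kmer_hashes(seq: str, k: int) -> np.ndarray:
    """Hashes of all valid canonical k-mers of ``seq``, in sequence order."""
    canon, valid = _packed_kmers(encode(seq), k)
    return mix64(canon[valid])


def kmer_counts(seq: str, k: int, counts: dict[int, int] | None = None) -> dict[int, int]:
    """Accumulate canonical k-mer hash counts of ``seq`` into a dict."""
    if counts is None:
        counts = {}
    hashes, freq = np.unique(canonical_kmer_hashes(seq, k), return_counts=True)
    for h, c in zip(hashes.tolist(), freq.tolist()):
        counts[h] = counts.get(h, 0) + c
    return counts


def extract_minimizers(seq: str, w: int = 10, k: int = 15) -> list[tuple[int, int]]:
    """(w,k)-minimizers of ``seq`` as (position, hash), deduplicated.

    Within each window of w consecutive k-mer starts the k-mer with the
    minimal hash is selected (leftmost on ties); consecutive selections of
    the same position are reported once.  The expected number of minimizers
    of an L-bp sequence is about 2L/(w+1).
    """
    if w < 1 or k < 1:
        raise ValueError("w and k must be positive")
    if k > 31:
        raise ValueError("k must be at most 31")
    canon, valid = _packed_kmers(encode(seq), k)
    n = canon.size
    if n == 0:
        return []
    hashes = mix64(canon)
    # invalid k-mers never win a window
    key = np.where(valid, hashes, _MASK64)
    if n <= w:
        if not valid.any():
            return []
        pos = int(np.argmin(key))
        return [(pos, int(hashes[pos]))]
    wins = np.lib.stride_tricks.sliding_window_view(key, w)
    arg = wins.argmin(axis=1)  # argmin is leftmost on ties
    pos = arg + np.arange(wins.shape[0])
    out: list[tuple[int, int]] = []
    last = -1
    for p in pos.tolist():
        if p != last:
            last = p
            if valid[p]:
                out.append((p, int(hashes[p])))
    return out


def minimizer_hashes(seq: str, w: int = 10, k: int = 15) -> list[int]:
    return [h for _, h in extract_minimizers(seq, w, k)]
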
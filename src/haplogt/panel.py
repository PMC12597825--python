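"""Locus haplotype panels, window tiling and genotype enumeration.

A target locus is represented by a panel of full-length haplotype sequences
(one FASTA record per haplotype).  Each haplotype is tiled with fixed-size
non-overlapping windows; every window carries the features that feed the
read-depth likelihood and the window weight:

* ``gc``   — GC fraction of an area centered around the window,
* ``x1``   — fraction of locus-specific k-mers in that area (k-mers with
  zero off-target multiplicity),
* ``x2``   — linguistic complexity of the window sequence (U1*U2*U3),
* ``zeta`` — window weight ζ_w = ϑ(x1; η1, q1) · ϑ(x2; η2, q2).

Each haplotype additionally owns one *null* window that absorbs read ends
without a proper alignment.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import kmers

DEFAULT_WINDOW_SIZE = 100
DEFAULT_KMER_SIZE = 25

# Window-weight defaults: break points and slopes of the two sigmoid factors.
ETA1, Q1 = 0.2, 4.0
ETA2, Q2 = 0.5, 4.0


def window_weight(x: float, eta: float, q: float) -> float:
    """Parametric weight function ϑ(x; η, q) mapping [0, 1] onto [0, 1].

    Strictly increasing and smooth on (0, 1] with ϑ(0) = 0, ϑ(1) = 1 and a
    break point ϑ(η) = 1/2 for every power q.  η locates the break point and
    q controls the slope there.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"x must be in [0, 1], got {x}")
    if not 0.0 < eta < 1.0:
        raise ValueError(f"eta must be in (0, 1), got {eta}")
    if x == 0.0:
        return 0.0
    if x == 1.0:
        return 1.0
    ratio = (eta / x) * ((1.0 - x) / (1.0 - eta))
    return 1.0 / (ratio**q + 1.0)


def linguistic_complexity(seq: str) -> float:
    """Linguistic sequence complexity x2 = U1 * U2 * U3.

    U_i is the number of distinct i-mers observed in ``seq`` divided by the
    maximal possible number of distinct i-mers, min(4^i, len(seq) - i + 1).
    i-mers containing N are excluded from the numerator, and positions whose
    i-mer contains N do not count toward the denominator.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    prod = 1.0
    for i in (1, 2, 3):
        if len(seq) < i:
            return 0.0
        imers = [seq[j : j + i] for j in range(len(seq) - i + 1)]
        valid = [m for m in imers if "N" not in m]
        if not valid:
            return 0.0
        denom = min(4**i, len(valid))
        prod *= len(set(valid)) / denom
    return prod


def gc_content(seq: str) -> float:
    """GC fraction over A/C/G/T bases only; 0.5 for sequences without them."""
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.5
    return (seq.count("G") + seq.count("C")) / acgt


@dataclass
class Haplotype:
    """One full-length allele sequence of a target locus."""

    id: str
    seq: str
    locus_id: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("haplotype id must be non-empty")
        if not self.seq:
            raise ValueError(f"haplotype {self.id}: empty sequence")
        self.seq = self.seq.upper()
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(f"haplotype {self.id}: invalid characters {bad}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Window:
    """One fixed-size window of a haplotype, or the haplotype's null window."""

    haplotype_id: str
    index: int
    start: int
    end: int
    gc: float = 0.5
    x1: float = 1.0
    x2: float = 1.0
    zeta: float = 1.0
    is_null: bool = False

    @classmethod
    def null(cls, haplotype_id: str) -> "Window":
        # zeta of the null window never enters the likelihood: its depth
        # status is considered uninformative (phi == 1).
        return cls(haplotype_id, -1, 0, 0, gc=float("nan"), x1=float("nan"),
                   x2=float("nan"), zeta=0.0, is_null=True)


@dataclass
class LocusPanel:
    """Reference haplotype set of one locus with optional per-base weights."""

    locus_id: str
    haplotypes: list[Haplotype]
    window_size: int = DEFAULT_WINDOW_SIZE
    explicit_weights: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.haplotypes:
            raise ValueError("panel needs at least one haplotype")
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        ids = [h.id for h in self.haplotypes]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate haplotype ids in locus {self.locus_id}")
        for hid, track in self.explicit_weights.items():
            hap = self.get(hid)
            if len(track) != len(hap):
                raise ValueError(
                    f"weight track for {hid} has length {len(track)}, "
                    f"haplotype has {len(hap)}")
            if np.any((track < 0) | (track > 1)):
                raise ValueError(f"weights for {hid} outside [0, 1]")

    def get(self, hap_id: str) -> Haplotype:
        for h in self.haplotypes:
            if h.id == hap_id:
                return h
        raise KeyError(f"no haplotype {hap_id} in locus {self.locus_id}")

    @property
    def haplotype_ids(self) -> list[str]:
        return [h.id for h in self.haplotypes]

    def __len__(self) -> int:
        return len(self.haplotypes)


@dataclass(frozen=True)
class Genotype:
    """Unordered pair of haplotype ids; h1 == h2 encodes a homozygote."""

    h1: str
    h2: str

    def __post_init__(self) -> None:
        if self.h2 < self.h1:
            a, b = self.h2, self.h1
            object.__setattr__(self, "h1", a)
            object.__setattr__(self, "h2", b)

    @property
    def ids(self) -> tuple[str, str]:
        return (self.h1, self.h2)

    def __str__(self) -> str:
        return f"{self.h1},{self.h2}"


def _neighborhood(start: int, end: int, window_size: int, seq_len: int) -> tuple[int, int]:
    """Window extended by half a window on each side, clipped at the ends."""
    pad = window_size // 2
    return max(0, start - pad), min(seq_len, end + pad)


def window_features(seq: str, start: int, end: int, window_size: int,
                    kmer_counts: Mapping[int, int] | None,
                    k: int = DEFAULT_KMER_SIZE) -> tuple[float, float, float]:
    """(gc, x1, x2) for the window [start, end) of ``seq``.

    gc and x1 are computed over the neighborhood centered on the window; x2
    over the window sequence itself.  x1 is the fraction of canonical k-mers
    in the neighborhood with zero off-target multiplicity; k-mers absent from
    ``kmer_counts`` count as locus-specific.
    """
    a, b = _neighborhood(start, end, window_size, len(seq))
    area = seq[a:b]
    gc = gc_content(area)
    if kmer_counts is None:
        x1 = 1.0
    else:
        hashes = kmers.canonical_kmer_hashes(area, k)
        if hashes.size == 0:
            x1 = 0.0
        else:
            specific = sum(1 for h in hashes.tolist() if kmer_counts.get(h, 0) == 0)
            x1 = specific / hashes.size
    x2 = linguistic_complexity(seq[start:end]) if end > start else 0.0
    return gc, x1, x2


def build_windows(panel: LocusPanel,
                  kmer_counts: Mapping[int, int] | None = None,
                  k: int = DEFAULT_KMER_SIZE,
                  eta1: float = ETA1, q1: float = Q1,
                  eta2: float = ETA2, q2: float = Q2,
                  ) -> dict[str, list[Window]]:
    """Tile every haplotype with non-overlapping fixed-size windows.

    Each haplotype receives floor(len / window_size) real windows starting at
    position 0 plus one null window (always the last element of its list).
    Trailing bases not covered by a full window belong to no window.  When a
    haplotype is shorter than the window size it only gets the null window.
    """
    ws = panel.window_size
    out: dict[str, list[Window]] = {}
    for hap in panel.haplotypes:
        n_win = len(hap.seq) // ws
        if n_win == 0:
            warnings.warn(
                f"haplotype {hap.id} shorter than window size {ws}: "
                "no real windows")
        windows: list[Window] = []
        track = panel.explicit_weights.get(hap.id)
        for i in range(n_win):
            start, end = i * ws, (i + 1) * ws
            gc, x1, x2 = window_features(hap.seq, start, end, ws, kmer_counts, k)
            zeta = window_weight(x1, eta1, q1) * window_weight(x2, eta2, q2)
            if track is not None:
                zeta *= float(np.mean(track[start:end]))
            windows.append(Window(hap.id, i, start, end, gc, x1, x2, zeta))
        windows.append(Window.null(hap.id))
        out[hap.id] = windows
    return out


def window_of(midpoint: float, n_real_windows: int, window_size: int) -> int:
    """Index of the real window containing an alignment midpoint.

    Midpoints in the uncovered trailing bases attach to the last window.
    Returns -1 when the haplotype has no real windows.
    """
    if n_real_windows == 0:
        return -1
    return min(int(midpoint // window_size), n_real_windows - 1)


def enumerate_genotypes(panel: LocusPanel) -> list[Genotype]:
    """All unordered haplotype pairs with repetition, lexicographic order."""
    ids = sorted(panel.haplotype_ids)
    return [Genotype(a, b) for a, b in
            itertools.combinations_with_replacement(ids, 2)]
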
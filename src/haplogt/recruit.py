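"""Minimizer index over target loci and read recruitment.

Reads are matched against per-locus minimizer sets.  Short reads are
recruited when a sufficient fraction of their informative minimizers match
the locus on *every* read end (0.7 single-end, 0.5 per end for pairs).
Long reads are recruited when some contiguous stretch of minimizers scores
at least the length-normalized threshold under +s/-s match/mismatch
scoring, evaluated with Kadane's maximum-subarray algorithm.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import kmers
from .panel import LocusPanel

UNINFORMATIVE_MIN_COUNT = 5


@dataclass
class RecruitParams:
    """Recruitment thresholds and long-read scoring parameters."""

    frac_single: float = 0.7
    frac_paired: float = 0.5
    s_plus: int = 3
    s_minus: int = -1
    subregion_len: int = 2000
    match_frac: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.frac_single <= 1 and 0 < self.frac_paired <= 1):
            raise ValueError("recruitment fractions must be in (0, 1]")
        if not (0 < self.match_frac <= 1):
            raise ValueError("match_frac must be in (0, 1]")
        if self.s_plus <= 0 or self.s_minus >= 0:
            raise ValueError("need s_plus > 0 > s_minus")


def long_read_threshold(params: RecruitParams, w: int = 10) -> int:
    """Minimal Kadane score for long-read recruitment.

    ceil(2L * (M(s+ - s-) + s-) / (w + 1)), where 2L/(w+1) is the expected
    number of (w,k)-minimizers in an L-bp subregion.
    """
    num = 2 * params.subregion_len * (
        params.match_frac * (params.s_plus - params.s_minus) + params.s_minus)
    if num <= 0:
        raise ValueError("degenerate recruitment parameters: threshold <= 0")
    return math.ceil(num / (w + 1))


def max_subarray(scores: Sequence[float]) -> float:
    """Kadane's maximum contiguous-subarray sum (0 for an empty input)."""
    best = 0.0
    cur = 0.0
    for s in scores:
        cur = max(s, cur + s)
        best = max(best, cur)
    return best


@dataclass
class MinimizerIndex:
    """Per-locus informative minimizer sets plus multiset counts."""

    w: int = 10
    k: int = 15
    locus_minimizers: dict[str, set[int]] = field(default_factory=dict)
    locus_counts: dict[str, Counter] = field(default_factory=dict)
    uninformative: set[int] = field(default_factory=set)
    # hashes that are present in some locus AND off-target-free (count 0);
    # used for the target-specific k-mer count of each read
    specific: dict[str, set[int]] = field(default_factory=dict)

    @classmethod
    def build(cls, panels: Iterable[LocusPanel], w: int = 10, k: int = 15,
              offtarget_counts: Mapping[int, int] | None = None,
              ) -> "MinimizerIndex":
        """Collect minimizers from every haplotype of every locus.

        Minimizers with off-target count >= 5 are uninformative and take no
        part in matching.  Minimizers with off-target count 0 are the
        locus-specific set used later to flag ambiguous reads.
        """
        idx = cls(w=w, k=k)
        off = offtarget_counts or {}
        for panel in panels:
            mins: set[int] = set()
            counts: Counter = Counter()
            for hap in panel.haplotypes:
                hs = kmers.minimizer_hashes(hap.seq, w, k)
                mins.update(hs)
                counts.update(hs)
            idx.locus_minimizers[panel.locus_id] = mins
            idx.locus_counts[panel.locus_id] = counts
            idx.specific[panel.locus_id] = {
                h for h in mins if off.get(h, 0) == 0}
        if off:
            idx.uninformative = {h for h, c in off.items()
                                 if c >= UNINFORMATIVE_MIN_COUNT}
            for mins in idx.locus_minimizers.values():
                mins -= idx.uninformative
        return idx

    def informative(self, hashes: Iterable[int]) -> set[int]:
        return {h for h in hashes if h not in self.uninformative}

    def target_specific_count(self, locus_id: str,
                              read_hashes: Iterable[int]) -> int:
        """Number of distinct read minimizers specific to this locus."""
        return len(set(read_hashes) & self.specific[locus_id])


def recruit_short(end_hashes: Sequence[Sequence[int]], index: MinimizerIndex,
                  params: RecruitParams | None = None,
                  paired: bool | None = None) -> set[str]:
    """Loci recruiting a short read from its per-end minimizer hashes.

    A locus recruits the read iff, for every end, the fraction of that
    end's informative minimizers matching the locus reaches the threshold.
    Reads without informative minimizers are recruited nowhere.
    """
    params = params or RecruitParams()
    if paired is None:
        paired = len(end_hashes) > 1
    thresh = params.frac_paired if paired else params.frac_single
    ends = [index.informative(h) for h in end_hashes]
    if any(not e for e in ends):
        return set()
    out: set[str] = set()
    for locus, mins in index.locus_minimizers.items():
        if all(len(e & mins) / len(e) >= thresh for e in ends):
            out.add(locus)
    return out


def recruit_long(ordered_hashes: Sequence[int], index: MinimizerIndex,
                 params: RecruitParams | None = None) -> set[str]:
    """Loci recruiting a long read via Kadane maximum-subarray scoring.

    Informative minimizers score s_plus when they match the locus and
    s_minus otherwise; the read is recruited when the best contiguous
    stretch reaches the length-normalized threshold.
    """
    params = params or RecruitParams()
    thresh = long_read_threshold(params, index.w)
    inform = [h for h in ordered_hashes if h not in index.uninformative]
    out: set[str] = set()
    for locus, mins in index.locus_minimizers.items():
        scores = [params.s_plus if h in mins else params.s_minus
                  for h in inform]
        if max_subarray(scores) >= thresh:
            out.add(locus)
    return out


def offtarget_kmer_table(background_seqs: Iterable[str],
                         locus_ref_seqs: Iterable[str],
                         k: int = 25) -> dict[int, int]:
    """Off-target multiplicities: genome-wide canonical k-mer counts minus
    counts inside the reference locus sequences, floored at zero.

    k-mers absent from the returned table have off-target multiplicity 0
    (either locus-balanced or entirely novel).
    """
    counts: dict[int, int] = {}
    for seq in background_seqs:
        kmers.kmer_counts(seq, k, counts)
    locus: dict[int, int] = {}
    for seq in locus_ref_seqs:
        kmers.kmer_counts(seq, k, locus)
    out: dict[int, int] = {}
    for h, c in counts.items():
        off = c - locus.get(h, 0)
        if off > 0:
            out[h] = off
    return out
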
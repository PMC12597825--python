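"""Evaluation of predicted against true haplotypes with corrected QV.

The divergence of two haplotype sequences is summarized by the unit-cost
global edit distance Δ and the alignment size S (Δ plus the number of
matched bases).  The Phred-like quality value uses a corrected definition,

    QV = -10 * log10(max{Δ, 1/2} / S),

so identical sequences get a finite QV and the step between edit distances
0 and 1 equals the step between 1 and 2 (10 * log10 2 ≈ 3).

Diploid predictions are scored under the actual-vs-predicted pairing that
minimizes the pooled divergence ΣΔ / ΣS; trio concordance likewise searches
the eight child-to-parent haplotype assignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import edlib

from .align import _parse_extended_cigar

QV_BINS = (17.0, 23.0, 33.0, 43.0)
QV_BIN_LABELS = ("<17", "17-23", "23-33", "33-43", ">=43")


def global_align(a: str, b: str) -> tuple[int, int]:
    """(Δ, S): unit-cost global edit distance and alignment size.

    S counts matched bases plus every edit operation of an optimal global
    alignment.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    res = edlib.align(a.upper(), b.upper(), mode="NW", task="path")
    m, x, i, d = _parse_extended_cigar(res["cigar"])
    delta = x + i + d
    assert delta == res["editDistance"]
    return delta, delta + m


def corrected_qv(delta: int, size: int) -> float:
    """Corrected quality value, finite at Δ = 0."""
    if size <= 0:
        raise ValueError("alignment size must be positive")
    if delta < 0 or delta > size:
        raise ValueError("edit distance must be within [0, size]")
    return -10.0 * math.log10(max(delta, 0.5) / size)


def qv_bin(qv: float) -> str:
    """Half-open QV bins [17,23), [23,33), [33,43), [43,inf)."""
    for edge, label in zip(QV_BINS, QV_BIN_LABELS):
        if qv < edge:
            return label
    return QV_BIN_LABELS[-1]


@dataclass
class HaplotypeScore:
    delta: int
    size: int

    @property
    def qv(self) -> float:
        return corrected_qv(self.delta, self.size)

    @property
    def bin(self) -> str:
        return qv_bin(self.qv)


@dataclass
class PairingResult:
    """Chosen actual-to-predicted pairing with per-haplotype scores."""

    pairing: tuple[int, int]  # predicted index matched to actual 0, 1
    scores: tuple[HaplotypeScore, HaplotypeScore]

    @property
    def qvs(self) -> tuple[float, float]:
        return (self.scores[0].qv, self.scores[1].qv)

    @property
    def pooled_divergence(self) -> float:
        d = self.scores[0].delta + self.scores[1].delta
        s = self.scores[0].size + self.scores[1].size
        return d / s


def pair_and_score(actual: tuple[str, str],
                   predicted: tuple[str, str]) -> PairingResult:
    """Score a diploid prediction under its best haplotype pairing.

    Both pairings are aligned; the one with the smaller ratio of summed
    edit distance to summed alignment size wins.
    """
    results = []
    for pairing in ((0, 1), (1, 0)):
        scores = tuple(
            HaplotypeScore(*global_align(actual[i], predicted[pairing[i]]))
            for i in range(2))
        results.append(PairingResult(pairing, scores))
    return min(results, key=lambda r: r.pooled_divergence)


def trio_concordance(child: tuple[str, str],
                     mother: tuple[str, str],
                     father: tuple[str, str]) -> PairingResult:
    """Score a child's haplotypes against the best parental assignment.

    One child haplotype is matched to a maternal haplotype and the other to
    a paternal one; over the eight such combinations the assignment with
    the smallest pooled divergence ΣΔ / ΣS is selected and the per-child-
    haplotype QVs under it are reported (scores ordered as child
    haplotypes).
    """
    # cache alignments: child hap x each parental hap
    parents = {"m": mother, "f": father}
    cache: dict[tuple[int, str, int], HaplotypeScore] = {}
    for ci in range(2):
        for side, haps in parents.items():
            for pi in range(2):
                cache[(ci, side, pi)] = HaplotypeScore(
                    *global_align(child[ci], haps[pi]))
    best: PairingResult | None = None
    for first_side in ("m", "f"):
        other_side = "f" if first_side == "m" else "m"
        for pi in range(2):
            for pj in range(2):
                s0 = cache[(0, first_side, pi)]
                s1 = cache[(1, other_side, pj)]
                cand = PairingResult((pi, pj), (s0, s1))
                if best is None or cand.pooled_divergence < best.pooled_divergence:
                    best = cand
    assert best is not None
    return best
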
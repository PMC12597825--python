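"""Genotype likelihood: read-location probabilities, depth posteriors and
the combined log-likelihood with constant-time updates.

For every recruited read (pair) r and every haplotype h, each combination of
candidate alignments of the read ends yields one *location*.  The location
probability multiplies the per-end alignment likelihoods with the insert
size probability; ends without a proper alignment to h attach to the
haplotype's null window with the best achievable alignment probability
penalized by a factor Λ, and an optimal insert term (so unpaired locations
are penalized exactly once).  Location probabilities are normalized across
all haplotypes of the panel.

A diploid genotype g = (h1, h2) concatenates the two haplotypes' windows
and locations (two copies when h1 = h2).  Given a Boolean assignment T of
one location per read, the combined log-likelihood is

    L_T = Ω_R Σ_r wt_r log P(location of r) + Ω_D Σ_w ζ_w log φ_w(d_w(T))

where d_w counts read ends assigned to window w and φ_w(d) is the
posterior probability of copy number 1 given depth d under the GC-matched
negative binomial (alternative copy numbers {0.5, 1.5} with equal priors).
Moving a single read between locations updates L_T in constant time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import nbinom

from .align import ReadAlignments
from .panel import Genotype, Haplotype, Window, window_of
from .profiles import DepthModel, ErrorProfile, InsertSizeModel

NULL_PENALTY = 1e-5        # Λ: penalty factor of null-window attachment
OMEGA_R = 0.15             # contribution factor of read alignments
OMEGA_D = 1.85             # contribution factor of read depth
C_ALT = (0.5, 1.5)         # alternative copy-number hypotheses
MIN_TARGET_KMERS = 5       # below this, read locations become equiprobable


# -- per-read locations across all haplotypes ---------------------------------

@dataclass
class HapCombos:
    """Locations of one read on one haplotype (alignment granularity).

    ``mid1``/``mid2`` hold alignment midpoints, NaN marking the null window;
    ``logp`` holds the location log-probability (unnormalized at build time,
    normalized across all haplotypes afterwards).
    """

    hap_id: str
    mid1: np.ndarray
    mid2: np.ndarray
    logp: np.ndarray


@dataclass
class ReadLocations:
    """All candidate locations of one read (pair) across the panel."""

    read_id: str
    paired: bool
    weight: float = 1.0
    combos: dict[str, HapCombos] = field(default_factory=dict)

    @property
    def n_locations(self) -> int:
        return sum(c.logp.size for c in self.combos.values())

    def total_prob(self) -> float:
        return float(np.exp(logsumexp(
            np.concatenate([c.logp for c in self.combos.values()]))))


def paired_location_log_prob(lp1: float, lp2: float,
                             insert: int | None,
                             insert_model: InsertSizeModel | None) -> float:
    """Unnormalized log P(r, w): per-end alignment terms plus insert term.

    ``insert=None`` marks a location involving a null window, whose insert
    size is assumed optimal (log-pmf at the NB mode).
    """
    lp = lp1 + lp2
    if insert_model is not None:
        if insert is None:
            lp += insert_model.mode_log_pmf
        else:
            lp += insert_model.log_pmf(insert)
    return lp


def build_read_locations(read: ReadAlignments,
                         hap_ids: Sequence[str],
                         insert_model: InsertSizeModel | None,
                         null_penalty: float = NULL_PENALTY,
                         ) -> ReadLocations:
    """Enumerate and normalize all locations of one read across the panel.

    Reads with fewer than five target-specific k-mers get equal
    probabilities on all their locations, neutralizing potentially
    misrecruited reads from homologous regions elsewhere in the genome.
    """
    ends = read.end_ids
    paired = len(ends) == 2
    log_lambda = math.log(null_penalty)
    best = {e: read.best_log_prob(e) for e in ends}
    null_lp = {e: log_lambda + best[e] for e in ends}
    by_hap = {e: read.by_hap(e) for e in ends}
    loc = ReadLocations(read.read_id, paired, read.weight)
    for hap in hap_ids:
        mid1: list[float] = []
        mid2: list[float] = []
        lps: list[float] = []
        if paired:
            e1, e2 = ends
            a1 = by_hap[e1].get(hap, [])
            a2 = by_hap[e2].get(hap, [])
            for r1 in a1:
                for r2 in a2:
                    lo = min(r1.start, r2.start)
                    hi = max(r1.end_pos, r2.end_pos)
                    mid1.append(r1.midpoint)
                    mid2.append(r2.midpoint)
                    lps.append(paired_location_log_prob(
                        r1.log_prob, r2.log_prob, hi - lo, insert_model))
            for r1 in a1:
                mid1.append(r1.midpoint)
                mid2.append(math.nan)
                lps.append(paired_location_log_prob(
                    r1.log_prob, null_lp[e2], None, insert_model))
            for r2 in a2:
                mid1.append(math.nan)
                mid2.append(r2.midpoint)
                lps.append(paired_location_log_prob(
                    null_lp[e1], r2.log_prob, None, insert_model))
            mid1.append(math.nan)
            mid2.append(math.nan)
            lps.append(paired_location_log_prob(
                null_lp[e1], null_lp[e2], None, insert_model))
        else:
            e = ends[0]
            for r1 in by_hap[e].get(hap, []):
                mid1.append(r1.midpoint)
                mid2.append(math.nan)
                lps.append(r1.log_prob)
            mid1.append(math.nan)
            mid2.append(math.nan)
            lps.append(null_lp[e])
        loc.combos[hap] = HapCombos(
            hap, np.asarray(mid1), np.asarray(mid2), np.asarray(lps))
    normalize_locations(loc,
                        equalize=(read.target_specific_kmers is not None
                                  and read.target_specific_kmers < MIN_TARGET_KMERS))
    return loc


def normalize_locations(loc: ReadLocations, equalize: bool = False) -> None:
    """Normalize location log-probabilities across all haplotypes in place."""
    total = loc.n_locations
    if total == 0:
        raise ValueError(f"read {loc.read_id} has no locations")
    if equalize:
        flat = -math.log(total)
        for c in loc.combos.values():
            c.logp = np.full_like(c.logp, flat)
        return
    z = logsumexp(np.concatenate([c.logp for c in loc.combos.values()]))
    for c in loc.combos.values():
        c.logp = c.logp - z


# -- per-haplotype window tables ----------------------------------------------

def log_phi_row(n: float, psi: float, dcap: int,
                c_alt: Sequence[float] = C_ALT) -> np.ndarray:
    """log φ(d) for d = 0..dcap: posterior of CN=1 vs alternatives.

    φ(d) = NB(d; n, ψ) / Σ_{c in {1} ∪ C_alt} NB(d; c n, ψ), equal priors.
    """
    d = np.arange(dcap + 1)
    rows = [nbinom.logpmf(d, c * n, psi) for c in (1.0, *c_alt)]
    stack = np.vstack(rows)
    return rows[0] - logsumexp(stack, axis=0)


@dataclass
class HapTable:
    """Window weights and depth log-posteriors of one haplotype.

    Row layout: ``n_real`` real windows followed by the null window, whose
    ζ is 0 and whose log φ row is identically zero — the depth status of
    unattached read ends is uninformative, they are already penalized
    through Λ in the alignment term.
    """

    hap_id: str
    n_real: int
    window_size: int
    hap_len: int
    zeta: np.ndarray
    logphi: np.ndarray  # (n_real + 1, dcap + 1)

    @property
    def null_index(self) -> int:
        return self.n_real

    def attach(self, midpoint: float, shift: float = 0.0) -> int:
        """Window index of a (possibly jittered) alignment midpoint."""
        if math.isnan(midpoint):
            return self.null_index
        mid = min(max(midpoint + shift, 0.0), self.hap_len - 1)
        w = window_of(mid, self.n_real, self.window_size)
        return self.null_index if w < 0 else w


def build_hap_table(hap: Haplotype, windows: Sequence[Window],
                    depth_model: DepthModel, dcap: int,
                    gc_overrides: Mapping[int, float] | None = None,
                    zeta_overrides: Mapping[int, float] | None = None,
                    ) -> HapTable:
    """Assemble the per-window ζ / log φ table of one haplotype.

    ``gc_overrides`` / ``zeta_overrides`` substitute per-window features,
    used by the noise-injection replicates where window features are
    recomputed as if the window had been shifted.
    """
    real = [w for w in windows if not w.is_null]
    n_real = len(real)
    zeta = np.zeros(n_real + 1)
    logphi = np.zeros((n_real + 1, dcap + 1))
    cache: dict[tuple[float, float], np.ndarray] = {}
    for i, w in enumerate(real):
        gc = gc_overrides[i] if gc_overrides is not None else w.gc
        zeta[i] = zeta_overrides[i] if zeta_overrides is not None else w.zeta
        params = depth_model.params(gc)
        if params not in cache:
            cache[params] = log_phi_row(params[0], params[1], dcap)
        logphi[i] = cache[params]
    return HapTable(hap.id, n_real, depth_model.window_size, len(hap.seq),
                    zeta, logphi)


# -- genotype-level problem and assignment state ------------------------------

@dataclass
class GenotypeProblem:
    """Concrete optimization instance for one genotype.

    Combined window layout: h1 windows (real + null), then h2 windows
    (real + null) — two copies when h1 = h2.  Per read, the location arrays
    give the two window indices (-1 when the read is single-end) and the
    weighted normalized log-location-probability.
    """

    genotype: Genotype
    zeta: np.ndarray
    logphi: np.ndarray
    read_w1: list[np.ndarray]
    read_w2: list[np.ndarray]
    read_wlogp: list[np.ndarray]  # weight * normalized log P, per location
    omega_r: float = OMEGA_R
    omega_d: float = OMEGA_D

    @property
    def n_reads(self) -> int:
        return len(self.read_w1)

    @property
    def n_windows(self) -> int:
        return self.zeta.size

    def n_locations(self, r: int) -> int:
        return self.read_w1[r].size


def build_problem(genotype: Genotype,
                  reads: Sequence[ReadLocations],
                  tables: Mapping[str, HapTable],
                  omega_r: float = OMEGA_R,
                  omega_d: float = OMEGA_D,
                  shifts: Mapping[str, tuple[float, float]] | None = None,
                  ) -> GenotypeProblem:
    """Instantiate the assignment problem of one genotype.

    ``shifts`` optionally maps read ids to per-end midpoint shifts applied
    when attaching alignments to windows (noise injection).
    """
    t1, t2 = tables[genotype.h1], tables[genotype.h2]
    off2 = t1.n_real + 1
    zeta = np.concatenate([t1.zeta, t2.zeta])
    logphi = np.vstack([t1.logphi, t2.logphi])
    read_w1: list[np.ndarray] = []
    read_w2: list[np.ndarray] = []
    read_wlogp: list[np.ndarray] = []
    for loc in reads:
        w1: list[int] = []
        w2: list[int] = []
        lp: list[float] = []
        s1, s2 = shifts.get(loc.read_id, (0.0, 0.0)) if shifts else (0.0, 0.0)
        for table, offset in ((t1, 0), (t2, off2)):
            combo = loc.combos[table.hap_id]
            for m1, m2, l in zip(combo.mid1, combo.mid2, combo.logp):
                w1.append(offset + table.attach(m1, s1))
                if loc.paired:
                    w2.append(offset + table.attach(m2, s2))
                else:
                    w2.append(-1)
                lp.append(l)
        read_w1.append(np.asarray(w1, dtype=np.int64))
        read_w2.append(np.asarray(w2, dtype=np.int64))
        read_wlogp.append(np.asarray(lp) * loc.weight)
    return GenotypeProblem(genotype, zeta, logphi, read_w1, read_w2,
                           read_wlogp, omega_r, omega_d)


class AssignmentState:
    """One read assignment T with cached depths and log-likelihood."""

    def __init__(self, problem: GenotypeProblem, choice: np.ndarray) -> None:
        self.problem = problem
        self.choice = np.asarray(choice, dtype=np.int64).copy()
        self.depth = self._depth_from_choice()
        self.loglik = self.loglik_from_scratch()

    @classmethod
    def random(cls, problem: GenotypeProblem, rng: np.random.Generator
               ) -> "AssignmentState":
        choice = np.array([rng.integers(problem.n_locations(r))
                           for r in range(problem.n_reads)])
        return cls(problem, choice)

    @classmethod
    def argmax(cls, problem: GenotypeProblem) -> "AssignmentState":
        """Assign every read to its most probable location (depth-blind)."""
        choice = np.array([int(np.argmax(problem.read_wlogp[r]))
                           for r in range(problem.n_reads)])
        return cls(problem, choice)

    def _depth_from_choice(self) -> np.ndarray:
        p = self.problem
        depth = np.zeros(p.n_windows, dtype=np.int64)
        for r, j in enumerate(self.choice):
            depth[p.read_w1[r][j]] += 1
            w2 = p.read_w2[r][j]
            if w2 >= 0:
                depth[w2] += 1
        return depth

    def loglik_from_scratch(self) -> float:
        p = self.problem
        align_term = sum(p.read_wlogp[r][j]
                         for r, j in enumerate(self.choice))
        d = np.minimum(self.depth, p.logphi.shape[1] - 1)
        depth_term = float(np.dot(p.zeta, p.logphi[np.arange(p.n_windows), d]))
        return p.omega_r * float(align_term) + p.omega_d * depth_term

    # -- constant-time updates ------------------------------------------------

    def _depth_changes(self, r: int, j_new: int) -> dict[int, int]:
        p = self.problem
        j_old = self.choice[r]
        changes: dict[int, int] = {}
        for w, dc in ((p.read_w1[r][j_old], -1), (p.read_w2[r][j_old], -1),
                      (p.read_w1[r][j_new], +1), (p.read_w2[r][j_new], +1)):
            if w >= 0:
                changes[w] = changes.get(w, 0) + dc
        return {w: c for w, c in changes.items() if c != 0}

    def delta(self, r: int, j_new: int) -> float:
        """Log-likelihood change of moving read r to location j_new."""
        p = self.problem
        j_old = self.choice[r]
        if j_new == j_old:
            return 0.0
        d_align = p.omega_r * (p.read_wlogp[r][j_new] - p.read_wlogp[r][j_old])
        d_depth = 0.0
        for w, c in self._depth_changes(r, j_new).items():
            z = p.zeta[w]
            if z == 0.0:
                continue
            d0 = self.depth[w]
            d_depth += z * (p.logphi[w, d0 + c] - p.logphi[w, d0])
        return float(d_align) + p.omega_d * d_depth

    def move(self, r: int, j_new: int) -> float:
        """Apply a move, updating depths and the cached log-likelihood."""
        d = self.delta(r, j_new)
        for w, c in self._depth_changes(r, j_new).items():
            self.depth[w] += c
        self.choice[r] = j_new
        self.loglik += d
        return d

    def move_deltas(self, r: int) -> np.ndarray:
        """Vectorized deltas of moving read r to each of its locations."""
        p = self.problem
        j0 = self.choice[r]
        w1o, w2o = p.read_w1[r][j0], p.read_w2[r][j0]
        # depth with read r removed
        self.depth[w1o] -= 1
        if w2o >= 0:
            self.depth[w2o] -= 1
        base = np.empty(0)
        try:
            W1, W2 = p.read_w1[r], p.read_w2[r]
            d_align = p.omega_r * (p.read_wlogp[r] - p.read_wlogp[r][j0])
            drem1 = self.depth[W1]
            gain = p.zeta[W1] * (p.logphi[W1, drem1 + 1] - p.logphi[W1, drem1])
            has2 = W2 >= 0
            if has2.any():
                same = has2 & (W1 == W2)
                diff = has2 & ~same
                if diff.any():
                    Wd = W2[diff]
                    drem2 = self.depth[Wd]
                    gain[diff] += p.zeta[Wd] * (
                        p.logphi[Wd, drem2 + 1] - p.logphi[Wd, drem2])
                if same.any():
                    Ws = W1[same]
                    drs = self.depth[Ws]
                    gain[same] = p.zeta[Ws] * (
                        p.logphi[Ws, drs + 2] - p.logphi[Ws, drs])
            # loss of removing the read from its current windows
            loss = p.zeta[w1o] * (p.logphi[w1o, self.depth[w1o] + 1]
                                  - p.logphi[w1o, self.depth[w1o]])
            if w2o >= 0:
                if w2o == w1o:
                    loss = p.zeta[w1o] * (p.logphi[w1o, self.depth[w1o] + 2]
                                          - p.logphi[w1o, self.depth[w1o]])
                else:
                    loss += p.zeta[w2o] * (p.logphi[w2o, self.depth[w2o] + 1]
                                           - p.logphi[w2o, self.depth[w2o]])
            base = d_align + p.omega_d * (gain - loss)
        finally:
            self.depth[w1o] += 1
            if w2o >= 0:
                self.depth[w2o] += 1
        return base


def combined_loglik(problem: GenotypeProblem, choice: np.ndarray) -> float:
    """From-scratch combined log-likelihood of an assignment."""
    return AssignmentState(problem, choice).loglik
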
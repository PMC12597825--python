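"""Optional numba-compiled inner loops for the stochastic solvers.

The greedy and simulated-annealing solvers spend almost all their time in
single-read move evaluations.  This module provides flat-array kernels for
those loops, compiled with numba when it is installed; :mod:`solvers` falls
back to the pure-Python reference implementation otherwise.  The kernels
evaluate each move by applying its depth changes to at most four windows,
reading the ζ-weighted log φ difference and reverting, so their arithmetic
is identical to :meth:`haplogt.likelihood.AssignmentState.delta`.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


def flatten_problem(problem):
    """Concatenate a problem's per-read location arrays for the kernels."""
    n_reads = problem.n_reads
    loc_off = np.zeros(n_reads + 1, dtype=np.int64)
    for r in range(n_reads):
        loc_off[r + 1] = loc_off[r] + problem.n_locations(r)
    w1 = np.concatenate(problem.read_w1) if n_reads else np.zeros(0, np.int64)
    w2 = np.concatenate(problem.read_w2) if n_reads else np.zeros(0, np.int64)
    wlogp = (np.concatenate(problem.read_wlogp) if n_reads
             else np.zeros(0))
    return (loc_off, w1.astype(np.int64), w2.astype(np.int64),
            wlogp.astype(np.float64))


@njit(cache=True)
def _move_delta(r, jn_abs, loc_off, w1, w2, wlogp, zeta, logphi, choice,
                depth, omega_r, omega_d):
    """ΔL of moving read r to absolute location jn_abs (depth unchanged)."""
    jo_abs = loc_off[r] + choice[r]
    if jn_abs == jo_abs:
        return 0.0
    ws = np.empty(4, dtype=np.int64)
    dc = np.empty(4, dtype=np.int64)
    m = 0
    for w, c in ((w1[jo_abs], -1), (w2[jo_abs], -1),
                 (w1[jn_abs], 1), (w2[jn_abs], 1)):
        if w < 0:
            continue
        found = False
        for i in range(m):
            if ws[i] == w:
                dc[i] += c
                found = True
                break
        if not found:
            ws[m] = w
            dc[m] = c
            m += 1
    d_depth = 0.0
    for i in range(m):
        w, c = ws[i], dc[i]
        if c != 0 and zeta[w] != 0.0:
            d0 = depth[w]
            d_depth += zeta[w] * (logphi[w, d0 + c] - logphi[w, d0])
    return (omega_r * (wlogp[jn_abs] - wlogp[jo_abs]) + omega_d * d_depth)


@njit(cache=True)
def _apply_move(r, jn_abs, loc_off, w1, w2, choice, depth):
    jo_abs = loc_off[r] + choice[r]
    depth[w1[jo_abs]] -= 1
    if w2[jo_abs] >= 0:
        depth[w2[jo_abs]] -= 1
    depth[w1[jn_abs]] += 1
    if w2[jn_abs] >= 0:
        depth[w2[jn_abs]] += 1
    choice[r] = jn_abs - loc_off[r]


@njit(cache=True)
def _greedy_passes(loc_off, w1, w2, wlogp, zeta, logphi, choice, depth,
                   omega_r, omega_d):
    """Best-improving single-read moves until a full pass changes nothing."""
    n_reads = loc_off.size - 1
    total = 0.0
    improved = True
    while improved:
        improved = False
        order = np.random.permutation(n_reads)
        for i in range(n_reads):
            r = order[i]
            lo, hi = loc_off[r], loc_off[r + 1]
            if hi - lo < 2:
                continue
            best_j = -1
            best_d = 1e-12
            for j in range(lo, hi):
                d = _move_delta(r, j, loc_off, w1, w2, wlogp, zeta, logphi,
                                choice, depth, omega_r, omega_d)
                if d > best_d:
                    best_d = d
                    best_j = j
            if best_j >= 0:
                _apply_move(r, best_j, loc_off, w1, w2, choice, depth)
                total += best_d
                improved = True
    return total


@njit(cache=True)
def _depth_from_choice(loc_off, w1, w2, choice, n_windows):
    depth = np.zeros(n_windows, dtype=np.int64)
    for r in range(loc_off.size - 1):
        j = loc_off[r] + choice[r]
        depth[w1[j]] += 1
        if w2[j] >= 0:
            depth[w2[j]] += 1
    return depth


@njit(cache=True)
def greedy_kernel(loc_off, w1, w2, wlogp, zeta, logphi, omega_r, omega_d,
                  n_windows, seed):
    """Random start plus best-improving passes; returns the final choice."""
    np.random.seed(seed)
    n_reads = loc_off.size - 1
    choice = np.zeros(n_reads, dtype=np.int64)
    for r in range(n_reads):
        choice[r] = np.random.randint(loc_off[r + 1] - loc_off[r])
    depth = _depth_from_choice(loc_off, w1, w2, choice, n_windows)
    _greedy_passes(loc_off, w1, w2, wlogp, zeta, logphi, choice, depth,
                   omega_r, omega_d)
    return choice


@njit(cache=True)
def sa_kernel(loc_off, w1, w2, wlogp, zeta, logphi, omega_r, omega_d,
              n_windows, seed, t0, cooling, blocks):
    """Simulated annealing with geometric cooling and greedy polish.

    ``t0 <= 0`` requests automatic calibration: the 90th percentile of
    |ΔL| over 100 random moves from the random start.  Returns the final
    choice; the caller recomputes the log-likelihood from scratch.
    """
    np.random.seed(seed)
    n_reads = loc_off.size - 1
    choice = np.zeros(n_reads, dtype=np.int64)
    n_movable = 0
    for r in range(n_reads):
        choice[r] = np.random.randint(loc_off[r + 1] - loc_off[r])
        if loc_off[r + 1] - loc_off[r] > 1:
            n_movable += 1
    depth = _depth_from_choice(loc_off, w1, w2, choice, n_windows)
    if n_movable == 0:
        return choice
    movable = np.empty(n_movable, dtype=np.int64)
    m = 0
    for r in range(n_reads):
        if loc_off[r + 1] - loc_off[r] > 1:
            movable[m] = r
            m += 1

    temp = t0
    if temp <= 0.0:
        samples = np.empty(100)
        for s in range(100):
            r = movable[np.random.randint(n_movable)]
            j = loc_off[r] + np.random.randint(loc_off[r + 1] - loc_off[r])
            samples[s] = abs(_move_delta(r, j, loc_off, w1, w2, wlogp, zeta,
                                         logphi, choice, depth,
                                         omega_r, omega_d))
        temp = max(np.percentile(samples, 90.0), 1e-6)

    cur = 0.0
    best = 0.0
    best_choice = choice.copy()
    steps_per_block = max(n_movable, 20)
    for _ in range(blocks):
        for _ in range(steps_per_block):
            r = movable[np.random.randint(n_movable)]
            j = loc_off[r] + np.random.randint(loc_off[r + 1] - loc_off[r])
            d = _move_delta(r, j, loc_off, w1, w2, wlogp, zeta, logphi,
                            choice, depth, omega_r, omega_d)
            if d >= 0 or np.random.random() < math.exp(d / temp):
                _apply_move(r, j, loc_off, w1, w2, choice, depth)
                cur += d
                if cur > best:
                    best = cur
                    best_choice[:] = choice
        temp *= cooling
    if best > cur:
        choice = best_choice
        depth = _depth_from_choice(loc_off, w1, w2, choice, n_windows)
    _greedy_passes(loc_off, w1, w2, wlogp, zeta, logphi, choice, depth,
                   omega_r, omega_d)
    return choice
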
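"""Read-assignment optimization: greedy, simulated annealing, ILP, brute.

All four solvers maximize the combined log-likelihood L_T of a
:class:`~haplogt.likelihood.GenotypeProblem`.  The stochastic greedy and
simulated-annealing solvers walk the assignment space with constant-time
likelihood updates; the ILP formulates the exact problem with one Boolean
location variable per (read, location) and one Boolean depth-level variable
per (window, depth) and hands it to the HiGHS mixed-integer backend; the
brute-force solver enumerates every assignment and serves as the test
oracle on tiny instances.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .likelihood import AssignmentState, GenotypeProblem


@dataclass
class SolverConfig:
    method: str = "sim_anneal"  # greedy | sim_anneal | ilp | brute
    seed: int = 0
    sa_t0: float | None = None     # None: set from sampled move deltas
    sa_cooling: float = 0.97
    sa_blocks: int = 20            # cooling blocks of n_reads steps each
    ilp_time_limit: float | None = None
    brute_limit: int = 1_000_000
    use_kernels: bool = True       # compiled inner loops when available

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    @property
    def kernels(self) -> bool:
        return self.use_kernels and _kernels.HAVE_NUMBA


def solve(problem: GenotypeProblem, config: SolverConfig | None = None
          ) -> AssignmentState:
    config = config or SolverConfig()
    fn = {"greedy": solve_greedy, "sim_anneal": solve_sim_anneal,
          "ilp": solve_ilp, "brute": solve_brute}.get(config.method)
    if fn is None:
        raise ValueError(f"unknown solver method {config.method!r}")
    return fn(problem, config)


def _greedy_pass(state: AssignmentState, order: np.ndarray) -> bool:
    """One sweep of best-improving moves; True if anything improved."""
    improved = False
    for r in order:
        if state.problem.n_locations(r) < 2:
            continue
        deltas = state.move_deltas(r)
        j = int(np.argmax(deltas))
        if deltas[j] > 1e-12:
            state.move(r, j)
            improved = True
    return improved


def _kernel_seed(config: SolverConfig) -> int:
    return int(config.seed) % (2 ** 32 - 1)


def solve_greedy(problem: GenotypeProblem,
                 config: SolverConfig | None = None) -> AssignmentState:
    """Stochastic greedy search: random start, best-improving single-read
    moves in random order until a full pass yields no improvement."""
    config = config or SolverConfig(method="greedy")
    if config.kernels:
        choice = _kernels.greedy_kernel(
            *_kernels.flatten_problem(problem), problem.zeta, problem.logphi,
            problem.omega_r, problem.omega_d, problem.n_windows,
            _kernel_seed(config))
        return AssignmentState(problem, choice)
    rng = config.rng()
    state = AssignmentState.random(problem, rng)
    while _greedy_pass(state, rng.permutation(problem.n_reads)):
        pass
    return state


def solve_sim_anneal(problem: GenotypeProblem,
                     config: SolverConfig | None = None) -> AssignmentState:
    """Simulated annealing with geometric cooling and a greedy polish.

    The initial temperature is the 90th percentile of |ΔL| over 100 random
    moves from the random start; each cooling block performs one move
    attempt per read.  The best-seen assignment is kept and finished with
    greedy passes so the returned state is a local optimum.
    """
    config = config or SolverConfig()
    if config.kernels:
        choice = _kernels.sa_kernel(
            *_kernels.flatten_problem(problem), problem.zeta, problem.logphi,
            problem.omega_r, problem.omega_d, problem.n_windows,
            _kernel_seed(config),
            -1.0 if config.sa_t0 is None else float(config.sa_t0),
            config.sa_cooling, config.sa_blocks)
        return AssignmentState(problem, choice)
    rng = config.rng()
    state = AssignmentState.random(problem, rng)
    movable = [r for r in range(problem.n_reads) if problem.n_locations(r) > 1]
    if not movable:
        return state
    if config.sa_t0 is not None:
        temp = config.sa_t0
    else:
        samples = []
        for _ in range(100):
            r = movable[rng.integers(len(movable))]
            j = int(rng.integers(problem.n_locations(r)))
            samples.append(abs(state.delta(r, j)))
        temp = max(float(np.percentile(samples, 90)), 1e-6)
    best_choice = state.choice.copy()
    best_loglik = state.loglik
    steps_per_block = max(len(movable), 20)
    for _ in range(config.sa_blocks):
        for _ in range(steps_per_block):
            r = movable[rng.integers(len(movable))]
            j = int(rng.integers(problem.n_locations(r)))
            d = state.delta(r, j)
            if d >= 0 or rng.random() < math.exp(d / temp):
                state.move(r, j)
                if state.loglik > best_loglik:
                    best_loglik = state.loglik
                    best_choice = state.choice.copy()
        temp *= config.sa_cooling
    if best_loglik > state.loglik:
        state = AssignmentState(problem, best_choice)
    while _greedy_pass(state, rng.permutation(problem.n_reads)):
        pass
    return state


def solve_brute(problem: GenotypeProblem,
                config: SolverConfig | None = None) -> AssignmentState:
    """Exhaustive enumeration of all assignments (test oracle)."""
    config = config or SolverConfig(method="brute")
    sizes = [problem.n_locations(r) for r in range(problem.n_reads)]
    total = 1
    for s in sizes:
        total *= s
        if total > config.brute_limit:
            raise ValueError(
                f"brute-force instance too large (> {config.brute_limit})")
    best: AssignmentState | None = None
    for combo in itertools.product(*(range(s) for s in sizes)):
        state = AssignmentState(problem, np.asarray(combo))
        if best is None or state.loglik > best.loglik:
            best = state
    assert best is not None
    return best


def solve_ilp(problem: GenotypeProblem,
              config: SolverConfig | None = None) -> AssignmentState:
    """Exact assignment via mixed-integer programming (HiGHS backend).

    Unknowns: x_rw per nontrivial read r and location w (reads with one
    location are eliminated and folded into constants), and y_wd per window
    w and feasible depth d.  Per window, depth ranges from the trivial-read
    baseline to the baseline plus the maximal contribution of nontrivial
    reads, so the number of depth levels is one more than the number of
    nontrivial read ends that can reach the window.  Constraints: one
    location per read, one depth level per window, and the linking
    constraint equating assigned read ends with the selected depth.
    """
    from scipy import optimize, sparse

    config = config or SolverConfig(method="ilp")
    p = problem
    n_reads = p.n_reads
    trivial = [r for r in range(n_reads) if p.n_locations(r) == 1]
    nontrivial = [r for r in range(n_reads) if p.n_locations(r) > 1]

    # baseline depth from trivial reads
    base_depth = np.zeros(p.n_windows, dtype=np.int64)
    for r in trivial:
        base_depth[p.read_w1[r][0]] += 1
        if p.read_w2[r][0] >= 0:
            base_depth[p.read_w2[r][0]] += 1
    # per window: maximal extra ends contributed by nontrivial reads
    max_extra = np.zeros(p.n_windows, dtype=np.int64)
    for r in nontrivial:
        contrib: dict[int, int] = {}
        for j in range(p.n_locations(r)):
            cnt: dict[int, int] = {}
            w1, w2 = p.read_w1[r][j], p.read_w2[r][j]
            cnt[w1] = cnt.get(w1, 0) + 1
            if w2 >= 0:
                cnt[w2] = cnt.get(w2, 0) + 1
            for w, c in cnt.items():
                contrib[w] = max(contrib.get(w, 0), c)
        for w, c in contrib.items():
            max_extra[w] += c

    # windows whose depth is undetermined need y variables
    model_windows = [w for w in range(p.n_windows)
                     if max_extra[w] > 0 and p.zeta[w] > 0]
    model_set = set(model_windows)
    const = 0.0
    for r in trivial:
        const += p.omega_r * float(p.read_wlogp[r][0])
    for w in range(p.n_windows):
        if w not in model_set and p.zeta[w] > 0:
            const += p.omega_d * p.zeta[w] * float(p.logphi[w, base_depth[w]])

    # variable layout: x blocks per nontrivial read, then y blocks per window
    x_offset: dict[int, int] = {}
    pos = 0
    for r in nontrivial:
        x_offset[r] = pos
        pos += p.n_locations(r)
    y_offset: dict[int, int] = {}
    y_levels: dict[int, np.ndarray] = {}
    for w in model_windows:
        y_offset[w] = pos
        levels = np.arange(base_depth[w], base_depth[w] + max_extra[w] + 1)
        y_levels[w] = levels
        pos += levels.size
    n_vars = pos
    if n_vars == 0:
        # every read has a single location: the assignment is forced
        state = AssignmentState(problem, np.zeros(n_reads, dtype=np.int64))
        state.optimal = True  # type: ignore[attr-defined]
        return state

    obj = np.zeros(n_vars)
    for r in nontrivial:
        o = x_offset[r]
        obj[o:o + p.n_locations(r)] = p.omega_r * p.read_wlogp[r]
    for w in model_windows:
        o = y_offset[w]
        obj[o:o + y_levels[w].size] = (
            p.omega_d * p.zeta[w] * p.logphi[w, y_levels[w]])

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    rhs_lo: list[float] = []
    rhs_hi: list[float] = []
    row = 0
    # one location per read
    for r in nontrivial:
        o = x_offset[r]
        for j in range(p.n_locations(r)):
            rows.append(row); cols.append(o + j); vals.append(1.0)
        rhs_lo.append(1.0); rhs_hi.append(1.0)
        row += 1
    # one depth level per window
    for w in model_windows:
        o = y_offset[w]
        for i in range(y_levels[w].size):
            rows.append(row); cols.append(o + i); vals.append(1.0)
        rhs_lo.append(1.0); rhs_hi.append(1.0)
        row += 1
    # depth linking: sum of assigned ends + baseline == selected depth level
    for w in model_windows:
        for r in nontrivial:
            o = x_offset[r]
            for j in range(p.n_locations(r)):
                c = int(p.read_w1[r][j] == w) + int(p.read_w2[r][j] == w)
                if c:
                    rows.append(row); cols.append(o + j); vals.append(float(c))
        o = y_offset[w]
        for i, d in enumerate(y_levels[w]):
            rows.append(row); cols.append(o + i); vals.append(-float(d))
        rhs_lo.append(-float(base_depth[w])); rhs_hi.append(-float(base_depth[w]))
        row += 1

    A = sparse.csr_array((vals, (rows, cols)), shape=(row, n_vars))
    constraints = optimize.LinearConstraint(A, rhs_lo, rhs_hi)
    options = {}
    if config.ilp_time_limit is not None:
        options["time_limit"] = config.ilp_time_limit
    res = optimize.milp(
        c=-obj, integrality=np.ones(n_vars),
        bounds=optimize.Bounds(0, 1), constraints=constraints,
        options=options)
    if res.x is None:
        raise RuntimeError(f"ILP solver failed: {res.message}")

    choice = np.zeros(n_reads, dtype=np.int64)
    for r in nontrivial:
        o = x_offset[r]
        choice[r] = int(np.argmax(res.x[o:o + p.n_locations(r)]))
    state = AssignmentState(problem, choice)
    state.optimal = bool(res.status == 0)  # type: ignore[attr-defined]
    return state
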
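"""Shared fixtures: synthetic profiles and random assignment problems."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from haplogt.panel import Genotype
from haplogt.likelihood import GenotypeProblem
from haplogt.profiles import DepthModel, ErrorProfile, InsertSizeModel


@pytest.fixture(scope="session")
def toy_error_profile() -> ErrorProfile:
    return ErrorProfile(bb_alpha=2.0, bb_beta=998.0,
                        p_match=0.996, p_mismatch=0.002,
                        p_ins=0.002, p_del=0.002)


@pytest.fixture(scope="session")
def toy_insert_model() -> InsertSizeModel:
    n, psi = 400.0, 400.0 / 900.0  # mean 500
    lo = int(stats.nbinom.ppf(0.0005, n, psi))
    hi = int(stats.nbinom.ppf(0.9995, n, psi))
    return InsertSizeModel(n=n, psi=psi, max_insert=3 * hi, ci999=(lo, hi))


@pytest.fixture(scope="session")
def toy_depth_model() -> DepthModel:
    # flat GC response: NB(n=10, psi=0.5), mean depth 10 per window
    return DepthModel(window_size=100,
                      table={g: (10.0, 0.5) for g in range(101)})


def random_problem(rng: np.random.Generator,
                   n_reads: int | None = None,
                   max_locations: int = 3,
                   n_windows: int = 8,
                   paired_fraction: float = 0.7) -> GenotypeProblem:
    """Arbitrary small assignment problem with no biological structure.

    Window indices, weights and depth posteriors are random, so solver
    agreement on these instances is evidence about the optimization code,
    not about any particular data regime.
    """
    if n_reads is None:
        n_reads = int(rng.integers(1, 6))
    dcap = 2 * n_reads + 2
    zeta = rng.random(n_windows)
    zeta[rng.random(n_windows) < 0.2] = 0.0
    logphi = -3.0 * rng.random((n_windows, dcap + 1))
    logphi[zeta == 0.0] = 0.0
    read_w1, read_w2, read_wlogp = [], [], []
    for _ in range(n_reads):
        n_loc = int(rng.integers(1, max_locations + 1))
        w1 = rng.integers(0, n_windows, size=n_loc)
        if rng.random() < paired_fraction:
            w2 = rng.integers(0, n_windows, size=n_loc)
        else:
            w2 = np.full(n_loc, -1)
        lp = -5.0 * rng.random(n_loc)
        read_w1.append(w1.astype(np.int64))
        read_w2.append(w2.astype(np.int64))
        read_wlogp.append(lp)
    return GenotypeProblem(Genotype("a", "b"), zeta, logphi,
                           read_w1, read_w2, read_wlogp)
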
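"""Combined log-likelihood: locations, depth posteriors, incremental updates."""

import math

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import nbinom

from haplogt.align import AlignmentRecord, ReadAlignments
from haplogt.likelihood import (NULL_PENALTY, AssignmentState, HapTable,
                                build_hap_table, build_read_locations,
                                combined_loglik, log_phi_row)
from haplogt.panel import Haplotype, LocusPanel, build_windows

from conftest import random_problem


def make_read(read_id="r", paired=True):
    """A read pair with alignments to haplotypes a (both ends) and b (one)."""
    a1 = AlignmentRecord(read_id, 1, "a", 100, 250, 148, 2, 0, 0,
                         log_prob=-3.0)
    a2 = AlignmentRecord(read_id, 2, "a", 400, 550, 150, 0, 0, 0,
                         log_prob=-1.0)
    b1 = AlignmentRecord(read_id, 1, "b", 90, 240, 145, 5, 0, 0,
                         log_prob=-8.0)
    if paired:
        return ReadAlignments(read_id, {1: [a1, b1], 2: [a2]})
    return ReadAlignments(read_id, {0: [a1, b1]})


class TestReadLocations:
    def test_normalization(self, toy_insert_model):
        loc = build_read_locations(make_read(), ["a", "b"], toy_insert_model)
        assert loc.total_prob() == pytest.approx(1.0, abs=1e-9)
        # per hap: a has 1 real-real + 1 real-null + 1 null-real + null-null
        assert loc.combos["a"].logp.size == 4
        # b has no end-2 alignment: only real-null and null-null remain
        assert loc.combos["b"].logp.size == 2

    def test_single_end_locations(self):
        loc = build_read_locations(make_read(paired=False), ["a", "b"], None)
        assert loc.combos["a"].logp.size == 2  # one alignment + null
        assert loc.combos["b"].logp.size == 2
        assert loc.total_prob() == pytest.approx(1.0, abs=1e-9)

    def test_null_penalty_factor(self):
        # single-end: null location log-prob = log(lambda) + best log-prob
        loc = build_read_locations(make_read(paired=False), ["a", "b"], None)
        raw_best = -3.0  # best alignment log-prob across the panel
        lps = np.concatenate([loc.combos["a"].logp, loc.combos["b"].logp])
        z = logsumexp([-3.0, -8.0,
                       math.log(NULL_PENALTY) + raw_best,
                       math.log(NULL_PENALTY) + raw_best])
        null_expected = math.log(NULL_PENALTY) + raw_best - z
        assert np.isnan(loc.combos["a"].mid1[-1])
        assert loc.combos["a"].logp[-1] == pytest.approx(null_expected)

    def test_ambiguous_read_equalized(self, toy_insert_model):
        read = make_read()
        read.target_specific_kmers = 2  # below the 5-k-mer threshold
        loc = build_read_locations(read, ["a", "b"], toy_insert_model)
        lps = np.concatenate([loc.combos["a"].logp, loc.combos["b"].logp])
        assert np.allclose(lps, -math.log(loc.n_locations))


class TestLogPhiRow:
    def test_matches_direct_formula(self):
        n, psi, dcap = 10.0, 0.5, 30
        row = log_phi_row(n, psi, dcap)
        for d in range(dcap + 1):
            num = nbinom.logpmf(d, n, psi)
            den = logsumexp([nbinom.logpmf(d, c * n, psi)
                             for c in (1.0, 0.5, 1.5)])
            assert row[d] == pytest.approx(float(num - den), abs=1e-10)

    def test_posterior_peaks_at_expected_depth(self):
        row = log_phi_row(10.0, 0.5, 40)  # mean depth 10
        assert int(np.argmax(row)) == pytest.approx(10, abs=2)
        assert row[0] < row[10] and row[35] < row[10]


class TestHapTable:
    def test_attach_maps_midpoints(self, toy_depth_model):
        rng = np.random.default_rng(61)
        seq = "".join(rng.choice(list("ACGT"), size=523))
        panel = LocusPanel("L", [Haplotype("h1", seq)], window_size=100)
        windows = build_windows(panel)["h1"]
        table = build_hap_table(panel.haplotypes[0], windows,
                                toy_depth_model, dcap=20)
        assert table.attach(50.0) == 0
        assert table.attach(450.0) == 4
        assert table.attach(510.0) == 4   # trailing bases -> last window
        assert table.attach(math.nan) == table.null_index
        assert table.attach(40.0, shift=70.0) == 1    # jitter moves window
        assert table.attach(40.0, shift=-100.0) == 0  # clamped at 0
        assert table.zeta[table.null_index] == 0.0
        assert np.all(table.logphi[table.null_index] == 0.0)


def loglik_oracle(problem, choice):
    """Direct evaluation of the combined log-likelihood definition."""
    align = sum(problem.read_wlogp[r][j] for r, j in enumerate(choice))
    depth = np.zeros(problem.n_windows, dtype=int)
    for r, j in enumerate(choice):
        depth[problem.read_w1[r][j]] += 1
        w2 = problem.read_w2[r][j]
        if w2 >= 0:
            depth[w2] += 1
    dterm = sum(problem.zeta[w] * problem.logphi[w, depth[w]]
                for w in range(problem.n_windows))
    return problem.omega_r * align + problem.omega_d * dterm


class TestAssignmentState:
    def test_from_scratch_matches_oracle(self):
        rng = np.random.default_rng(62)
        for _ in range(20):
            p = random_problem(rng)
            choice = np.array([rng.integers(p.n_locations(r))
                               for r in range(p.n_reads)])
            assert combined_loglik(p, choice) == pytest.approx(
                loglik_oracle(p, choice), abs=1e-9)

    def test_incremental_updates_track_scratch(self):
        rng = np.random.default_rng(63)
        for _ in range(10):
            p = random_problem(rng, n_reads=5, max_locations=4)
            state = AssignmentState.random(p, rng)
            for _ in range(100):
                r = int(rng.integers(p.n_reads))
                j = int(rng.integers(p.n_locations(r)))
                d = state.delta(r, j)
                before = state.loglik
                state.move(r, j)
                assert state.loglik == pytest.approx(before + d, abs=1e-9)
            assert state.loglik == pytest.approx(
                state.loglik_from_scratch(), abs=1e-6)

    def test_delta_equals_loglik_difference(self):
        rng = np.random.default_rng(64)
        p = random_problem(rng, n_reads=4, max_locations=3)
        state = AssignmentState.random(p, rng)
        for r in range(p.n_reads):
            for j in range(p.n_locations(r)):
                target = state.choice.copy()
                target[r] = j
                expected = combined_loglik(p, target) - state.loglik
                assert state.delta(r, j) == pytest.approx(expected, abs=1e-9)

    def test_move_deltas_vectorization(self):
        rng = np.random.default_rng(65)
        for _ in range(10):
            p = random_problem(rng, n_reads=5, max_locations=4)
            state = AssignmentState.random(p, rng)
            for r in range(p.n_reads):
                vec = state.move_deltas(r)
                for j in range(p.n_locations(r)):
                    assert vec[j] == pytest.approx(state.delta(r, j),
                                                   abs=1e-9)

    def test_move_and_move_back(self):
        rng = np.random.default_rng(66)
        p = random_problem(rng, n_reads=3, max_locations=3)
        state = AssignmentState.random(p, rng)
        start = state.loglik
        orig = state.choice.copy()
        for r in range(p.n_reads):
            j_old = orig[r]
            j_new = (j_old + 1) % p.n_locations(r)
            state.move(r, j_new)
            state.move(r, int(j_old))
        assert state.loglik == pytest.approx(start, abs=1e-9)
        assert np.array_equal(state.choice, orig)


def test_kernel_delta_matches_reference():
    from haplogt import _kernels
    if not _kernels.HAVE_NUMBA:
        pytest.skip("numba not installed")
    rng = np.random.default_rng(67)
    for _ in range(10):
        p = random_problem(rng, n_reads=4, max_locations=4)
        state = AssignmentState.random(p, rng)
        loc_off, w1, w2, wlogp = _kernels.flatten_problem(p)
        for r in range(p.n_reads):
            for j in range(p.n_locations(r)):
                got = _kernels._move_delta(
                    r, loc_off[r] + j, loc_off, w1, w2, wlogp, p.zeta,
                    p.logphi, state.choice, state.depth,
                    p.omega_r, p.omega_d)
                assert got == pytest.approx(state.delta(r, j), abs=1e-9)
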
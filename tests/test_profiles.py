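"""Insert-size, error and depth profile fitting."""

import numpy as np
import pytest
from scipy import stats

from haplogt.profiles import (DepthModel, ErrorProfile, WgsProfile,
                              fit_depth_model, fit_error_profile,
                              fit_insert_size, nb_moment_fit)


class TestNbMomentFit:
    def test_round_trip(self):
        n, psi = nb_moment_fit(50.0, 120.0)
        mean = n * (1 - psi) / psi
        var = n * (1 - psi) / psi ** 2
        assert mean == pytest.approx(50.0)
        assert var == pytest.approx(120.0)

    def test_underdispersed_fallback(self):
        n, psi = nb_moment_fit(50.0, 30.0)
        assert psi == pytest.approx(0.999)
        assert n * (1 - psi) / psi == pytest.approx(50.0)

    def test_invalid_mean(self):
        with pytest.raises(ValueError):
            nb_moment_fit(0.0, 1.0)


class TestInsertSize:
    def test_recovery_from_nb_draws(self):
        rng = np.random.default_rng(41)
        true_n, true_psi = 400.0, 400.0 / 900.0  # mean 500
        draws = stats.nbinom.rvs(true_n, true_psi, size=5000,
                                 random_state=rng)
        model = fit_insert_size(draws)
        assert model.mean == pytest.approx(500.0, rel=0.03)

    def test_outliers_discarded(self):
        rng = np.random.default_rng(42)
        draws = stats.nbinom.rvs(400, 4 / 9, size=2000,
                                 random_state=rng).tolist()
        spiked = draws + [100_000] * 3
        model = fit_insert_size(spiked)
        assert model.mean == pytest.approx(500.0, rel=0.05)
        assert not model.in_ci(100_000)

    def test_minimum_pairs(self):
        with pytest.raises(ValueError):
            fit_insert_size([500] * 99)

    def test_mode_log_pmf_is_maximal(self, toy_insert_model):
        m = toy_insert_model
        mode_lp = m.mode_log_pmf
        grid = np.arange(0, 2000)
        assert mode_lp == pytest.approx(
            max(m.log_pmf(int(d)) for d in grid), abs=1e-12)

    def test_ci_gates(self, toy_insert_model):
        lo, hi = toy_insert_model.ci999
        assert toy_insert_model.in_ci(lo) and toy_insert_model.in_ci(hi)
        assert not toy_insert_model.in_ci(lo - 1)
        assert not toy_insert_model.in_ci(hi + 1)


class TestErrorProfile:
    def test_bb_pvalue_tail_semantics(self, toy_error_profile):
        p = toy_error_profile
        assert p.bb_pvalue(0, 150) == 1.0
        # upper tail P(K >= k) computed directly from the distribution
        direct = stats.betabinom.sf(4, 150, p.bb_alpha, p.bb_beta)
        assert p.bb_pvalue(5, 150) == pytest.approx(float(direct), rel=1e-12)

    def test_bb_pvalue_monotone_decreasing(self, toy_error_profile):
        vals = [toy_error_profile.bb_pvalue(k, 150) for k in range(0, 20)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_alignment_log_prob_product_form(self, toy_error_profile):
        p = toy_error_profile
        lp = p.alignment_log_prob(100, 2, 1, 3)
        direct = (100 * np.log(p.p_match) + 2 * np.log(p.p_mismatch)
                  + np.log(p.p_ins) + 3 * np.log(p.p_del))
        assert lp == pytest.approx(float(direct), rel=1e-12)

    def test_fit_recovers_rates(self):
        rng = np.random.default_rng(43)
        n_reads, read_len = 3000, 150
        alpha, beta = 2.0, 998.0  # mean error rate 0.002
        recs = []
        for _ in range(n_reads):
            rate = stats.beta.rvs(alpha, beta, random_state=rng)
            errs = rng.binomial(read_len, rate)
            x = rng.binomial(errs, 0.8) if errs else 0
            rest = errs - x
            i = rng.binomial(rest, 0.5) if rest else 0
            d = rest - i
            recs.append((read_len, read_len - x - i, x, i, d))
        prof = fit_error_profile(recs)
        assert prof.bb_mean_rate == pytest.approx(alpha / (alpha + beta),
                                                  rel=0.2)
        total_errs = sum(x + i + d for _, _, x, i, d in recs)
        total_bases = n_reads * read_len
        obs = total_errs / total_bases
        assert prof.p_mismatch + prof.p_ins == pytest.approx(
            sum(x + i for _, _, x, i, _ in recs) / total_bases, rel=1e-6)


class TestDepthModel:
    def test_fit_recovers_constant_nb(self):
        rng = np.random.default_rng(44)
        true_n, true_psi = 10.0, 0.5  # mean 10
        records = []
        for _ in range(1000):
            gc = rng.uniform(0.3, 0.7)
            d = stats.nbinom.rvs(true_n, true_psi, random_state=rng)
            records.append((int(d), gc, 1.0))
        model = fit_depth_model(records, window_size=100)
        assert model.mean_depth(0.5) == pytest.approx(10.0, rel=0.1)

    def test_low_uniqueness_windows_excluded(self):
        rng = np.random.default_rng(45)
        good = [(int(stats.nbinom.rvs(10, 0.5, random_state=rng)),
                 rng.uniform(0.3, 0.7), 0.95) for _ in range(600)]
        bad = [(500, rng.uniform(0.3, 0.7), 0.5) for _ in range(200)]
        model = fit_depth_model(good + bad, window_size=100)
        assert model.mean_depth(0.5) == pytest.approx(10.0, rel=0.15)

    def test_too_few_windows_raises(self):
        with pytest.raises(ValueError):
            fit_depth_model([(10, 0.5, 1.0)] * 100, window_size=100)

    def test_binomial_thinning(self, toy_depth_model):
        half = toy_depth_model.at_rate(0.5)
        assert half.mean_depth(0.5) == pytest.approx(
            0.5 * toy_depth_model.mean_depth(0.5))
        # thinning an NB keeps it NB with the same n
        n, psi = half.params(0.5)
        assert n == pytest.approx(10.0)

    def test_gc_lookup_nearest(self):
        model = DepthModel(window_size=100, table={40: (8.0, 0.5),
                                                   60: (12.0, 0.5)})
        assert model.params(0.41) == (8.0, 0.5)
        assert model.params(0.59) == (12.0, 0.5)
        assert model.params(95) == (12.0, 0.5)


def test_wgs_profile_json_round_trip(toy_error_profile, toy_insert_model,
                                     toy_depth_model):
    prof = WgsProfile(insert=toy_insert_model, error=toy_error_profile,
                      depth=toy_depth_model)
    restored = WgsProfile.from_json(prof.to_json())
    assert restored.insert.mean == pytest.approx(toy_insert_model.mean)
    assert restored.error.bb_mean_rate == pytest.approx(
        toy_error_profile.bb_mean_rate)
    assert restored.depth.mean_depth(0.5) == pytest.approx(
        toy_depth_model.mean_depth(0.5))
    single = WgsProfile(insert=None, error=toy_error_profile,
                        depth=toy_depth_model)
    assert WgsProfile.from_json(single.to_json()).insert is None
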
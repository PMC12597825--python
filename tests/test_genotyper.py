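"""Genotype prefiltering, Welch-based quality and diagnostics."""

import math
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from haplogt.genotyper import (GenotypeResult, NoiseConfig,
                               prefilter_genotypes, quality_and_probability,
                               weighted_jaccard_distance, welch_p_greater)
from haplogt.likelihood import HapCombos, ReadLocations
from haplogt.panel import Genotype


def read_with_scores(scores: dict[str, float], read_id="r") -> ReadLocations:
    loc = ReadLocations(read_id, paired=True)
    for hap, lp in scores.items():
        loc.combos[hap] = HapCombos(hap, np.array([50.0]), np.array([60.0]),
                                    np.array([lp]))
    return loc


class TestPrefilter:
    def test_keeps_everything_when_few_candidates(self):
        haps = [f"h{i}" for i in range(6)]
        gts = [Genotype(a, b) for i, a in enumerate(haps)
               for b in haps[i:]]
        assert len(gts) == 21
        reads = [read_with_scores({h: -float(i) for i, h in enumerate(haps)})
                 for _ in range(5)]
        kept = prefilter_genotypes(gts, reads)
        assert len(kept) == len(gts)  # floor 500 covers all

    def test_cutoff_applies_beyond_floor(self):
        haps = ["good", "bad"]
        gts = [Genotype("good", "good"), Genotype("good", "bad"),
               Genotype("bad", "bad")]
        # each read strongly prefers "good": per-read gap 2000 in log space
        reads = [read_with_scores({"good": -1.0, "bad": -2001.0})
                 for _ in range(2)]
        kept = prefilter_genotypes(gts, reads, floor=1)
        # scores: gg = 0.15*2*(-1), gb same (max of pair), bb far below cutoff
        assert Genotype("good", "good") in kept
        assert Genotype("good", "bad") in kept
        assert Genotype("bad", "bad") not in kept

    def test_best_always_kept(self):
        gts = [Genotype("a", "a")]
        reads = [read_with_scores({"a": -5.0})]
        assert prefilter_genotypes(gts, reads) == gts


class TestWelch:
    def test_identical_distributions(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert welch_p_greater(a, a.copy()) == pytest.approx(0.5)

    def test_clear_separation(self):
        rng = np.random.default_rng(81)
        a = rng.normal(0.0, 1.0, 30)
        b = rng.normal(-20.0, 1.0, 30)
        assert welch_p_greater(a, b) > 0.999999
        assert welch_p_greater(b, a) < 1e-6

    def test_matches_direct_t_cdf(self):
        rng = np.random.default_rng(82)
        a = rng.normal(1.0, 2.0, 12)
        b = rng.normal(0.0, 3.0, 15)
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / (a.size - 1)
                               + vb ** 2 / (b.size - 1))
        assert welch_p_greater(a, b) == pytest.approx(
            float(stats.t.cdf(t, df)), rel=1e-9)

    def test_degenerate_variance(self):
        assert welch_p_greater(np.array([2.0, 2.0]),
                               np.array([1.0, 1.0])) == 1.0
        assert welch_p_greater(np.array([1.0, 1.0]),
                               np.array([2.0, 2.0])) == 0.0
        assert welch_p_greater(np.array([1.0, 1.0]),
                               np.array([1.0, 1.0])) == 0.5


class TestQualityAndProbability:
    def make_results(self, loglik_sets):
        return [GenotypeResult(Genotype(f"h{i}", f"h{i}"),
                               np.asarray(ls, dtype=float))
                for i, ls in enumerate(loglik_sets)]

    def test_single_candidate(self):
        res = self.make_results([[-10.0, -11.0]])
        quality_and_probability(res)
        assert res[0].quality == 1000.0
        assert res[0].probability == 1.0

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(83)
        sets = [rng.normal(-100.0, 2.0, 20),
                rng.normal(-130.0, 2.0, 20),
                rng.normal(-131.0, 2.0, 20)]
        res = self.make_results(sets)
        quality_and_probability(res)
        # direct recompute
        n = 3
        p = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    p[i, j] = welch_p_greater(sets[i], sets[j])
        for j in range(n):
            err = max(p[i, j] for i in range(n) if i != j)
            expected_q = min(-10.0 * math.log10(max(err, 1e-100)), 1000.0)
            assert res[j].quality == pytest.approx(expected_q)
        logw = [sum(math.log(max(1.0 - p[i, j], 1e-300))
                    for i in range(n) if i != j) for j in range(n)]
        w = np.exp(np.array(logw) - max(logw))
        w /= w.sum()
        for j in range(n):
            assert res[j].probability == pytest.approx(float(w[j]))
        # the dominant candidate wins almost all mass
        assert res[0].probability > 0.999

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(84)
        res = self.make_results([rng.normal(-100 - k, 3.0, 10)
                                 for k in range(5)])
        quality_and_probability(res)
        assert sum(r.probability for r in res) == pytest.approx(1.0)


def test_weighted_jaccard_distance():
    a = Counter({"a": 2, "b": 1})
    b = Counter({"a": 1, "c": 1})
    # sum(min) = 1, sum(max) = 2 + 1 + 1 = 4
    assert weighted_jaccard_distance(a, b) == pytest.approx(0.75)
    assert weighted_jaccard_distance(a, a) == 0.0
    assert weighted_jaccard_distance(Counter(), Counter()) == 0.0
    assert weighted_jaccard_distance(a, Counter({"z": 3})) == 1.0


def test_noise_config():
    cfg = NoiseConfig()
    assert cfg.replicates == 20
    assert cfg.shift_cap(100) == 50     # min(ws / 2, 200)
    assert cfg.shift_cap(1000) == 200
    assert NoiseConfig(max_shift=30).shift_cap(1000) == 30
    with pytest.raises(ValueError):
        NoiseConfig(replicates=1)


def test_genotype_result_statistics():
    r = GenotypeResult(Genotype("a", "b"),
                       np.array([-10.0, -12.0, -11.0]))
    assert r.mean == pytest.approx(-11.0)
    assert r.sd == pytest.approx(1.0)
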
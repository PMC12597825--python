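"""Window weights, linguistic complexity, window tiling and genotypes."""

import math

import numpy as np
import pytest

from haplogt.panel import (Genotype, Haplotype, LocusPanel, build_windows,
                           enumerate_genotypes, gc_content,
                           linguistic_complexity, window_of, window_weight)

PARAM_SETS = [(0.2, 4.0), (0.5, 4.0), (0.8, 2.0)]


def weight_oracle(x: float, eta: float, q: float) -> float:
    """Independent closed-form evaluation of the weight function."""
    if x == 0.0:
        return 0.0
    return 1.0 / ((eta * (1.0 - x) / (x * (1.0 - eta))) ** q + 1.0)


class TestWindowWeight:
    @pytest.mark.parametrize("eta,q", PARAM_SETS)
    def test_upper_endpoint(self, eta, q):
        assert window_weight(1.0, eta, q) == 1.0

    @pytest.mark.parametrize("eta,q", PARAM_SETS)
    def test_lower_endpoint(self, eta, q):
        assert window_weight(0.0, eta, q) == 0.0

    @pytest.mark.parametrize("eta,q", PARAM_SETS + [(0.35, 1.0), (0.9, 7.0)])
    def test_break_point_half(self, eta, q):
        assert window_weight(eta, eta, q) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("eta,q", PARAM_SETS)
    def test_strictly_increasing_on_grid(self, eta, q):
        xs = np.linspace(0.0, 1.0, 100)
        vals = [window_weight(float(x), eta, q) for x in xs]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("eta,q", PARAM_SETS)
    def test_matches_closed_form(self, eta, q):
        for x in np.linspace(0.01, 0.99, 23):
            assert window_weight(float(x), eta, q) == pytest.approx(
                weight_oracle(float(x), eta, q), rel=1e-12)

    def test_domain_validation(self):
        with pytest.raises(ValueError):
            window_weight(-0.1, 0.5, 2.0)
        with pytest.raises(ValueError):
            window_weight(1.1, 0.5, 2.0)
        with pytest.raises(ValueError):
            window_weight(0.5, 0.0, 2.0)


def complexity_oracle(seq: str) -> float:
    prod = 1.0
    for i in (1, 2, 3):
        imers = [seq[j:j + i] for j in range(len(seq) - i + 1)
                 if "N" not in seq[j:j + i]]
        if not imers:
            return 0.0
        prod *= len(set(imers)) / min(4 ** i, len(imers))
    return prod


class TestLinguisticComplexity:
    def test_homopolymer(self):
        # U1=1/4, U2=1/3, U3=1/2
        assert linguistic_complexity("AAAA") == pytest.approx(1 / 24)

    def test_maximal(self):
        assert linguistic_complexity("ACGT") == pytest.approx(1.0)

    def test_against_oracle_random(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(3, 60))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            assert linguistic_complexity(seq) == pytest.approx(
                complexity_oracle(seq), rel=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            linguistic_complexity("")


def test_gc_content():
    assert gc_content("GGCC") == 1.0
    assert gc_content("AATT") == 0.0
    assert gc_content("ACGT") == 0.5
    assert gc_content("NNNN") == 0.5  # no informative bases
    assert gc_content("GNA") == pytest.approx(0.5)


class TestGenotype:
    def test_sorted_ids(self):
        g = Genotype("b", "a")
        assert g.ids == ("a", "b")
        assert str(g) == "a,b"

    def test_unsorted_pair_stays_heterozygous(self):
        # regression: swapping ids must not collapse the pair
        g = Genotype("z", "a")
        assert g.h1 == "a" and g.h2 == "z"

    def test_homozygote(self):
        g = Genotype("a", "a")
        assert g.ids == ("a", "a")

    def test_enumeration_count(self):
        haps = [Haplotype(f"h{i}", "ACGT" * 30) for i in range(4)]
        panel = LocusPanel("L", haps, window_size=40)
        gts = enumerate_genotypes(panel)
        assert len(gts) == 10  # n(n+1)/2 for n=4
        assert len(set(g.ids for g in gts)) == 10
        assert all(g.h1 <= g.h2 for g in gts)


class TestWindows:
    def test_tiling(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=523))
        panel = LocusPanel("L", [Haplotype("h1", seq)], window_size=100)
        windows = build_windows(panel)["h1"]
        real = [w for w in windows if not w.is_null]
        assert len(real) == 5  # floor(523 / 100)
        assert [w.start for w in real] == [0, 100, 200, 300, 400]
        assert [w.end for w in real] == [100, 200, 300, 400, 500]
        assert windows[-1].is_null and windows[-1].zeta == 0.0

    def test_zeta_within_unit_interval(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        panel = LocusPanel("L", [Haplotype("h1", seq)], window_size=100)
        for w in build_windows(panel)["h1"]:
            if not w.is_null:
                assert 0.0 <= w.zeta <= 1.0

    def test_explicit_weights_reduce_zeta(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        base = LocusPanel("L", [Haplotype("h1", seq)], window_size=100)
        weighted = LocusPanel(
            "L", [Haplotype("h1", seq)], window_size=100,
            explicit_weights={"h1": np.full(400, 0.25)})
        zb = [w.zeta for w in build_windows(base)["h1"] if not w.is_null]
        zw = [w.zeta for w in build_windows(weighted)["h1"] if not w.is_null]
        for b, w in zip(zb, zw):
            assert w == pytest.approx(0.25 * b)

    def test_window_of(self):
        assert window_of(50.0, 5, 100) == 0
        assert window_of(499.0, 5, 100) == 4
        assert window_of(530.0, 5, 100) == 4  # trailing bases -> last window
        assert window_of(math.inf, 0, 100) == -1
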
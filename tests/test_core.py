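"""Unit and property tests for the Poincaré plot entropy family."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pnde.core import (
    PoincarePoints,
    RingPartition,
    build_poincare_points,
    de,
    distribution_entropy,
    nde,
    nne,
    nonextensive_params,
    partition_sector_rings,
    to_positive_series,
    tsallis_entropy,
)


def nde_bruteforce(series, W, delay=1):
    """Independent reference: per-point linear-scan binning + literal
    generalized-entropy sum with the positive sign convention."""
    s = [float(v) for v in series]
    smin = min(s)
    x = [v - smin for v in s]
    d = [np.sqrt(x[i] ** 2 + x[i + delay] ** 2) for i in range(len(x) - delay)]
    L_max = max(d)
    if L_max == 0:
        return 0.0
    dl = L_max / W
    counts = [0] * W
    for di in d:
        k = 0
        while k < W - 1 and di >= (k + 1) * dl:
            k += 1
        counts[k] += 1
    total = 0.0
    for k in range(W):
        p = counts[k] / len(d)
        q = 1.0 + L_max - k * dl - dl / 2.0
        if p > 0:
            total += (p - p ** q) / (q - 1.0)
    return total


class TestPositiveSeries:
    @pytest.mark.parametrize("raw, expected, offset", [
        ([-2, 0, 3], [0, 2, 5], -2.0),
        ([0, 1, 2], [0, 1, 2], 0.0),
        ([5, 5, 5], [0, 0, 0], 5.0),
    ])
    def test_min_subtraction(self, raw, expected, offset):
        pos = to_positive_series(raw)
        np.testing.assert_array_equal(pos.values, expected)
        assert pos.offset == offset
        assert pos.values.min() == 0.0

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            to_positive_series([1.0])
        with pytest.raises(ValueError):
            to_positive_series([1.0, np.nan])


class TestPoincarePoints:
    def test_direct_indexing(self):
        pts = build_poincare_points(to_positive_series([0, 2, 5]), delay=1)
        np.testing.assert_array_equal(pts.x, [0, 2])
        np.testing.assert_array_equal(pts.y, [2, 5])

    @pytest.mark.parametrize("n, delay, count", [(2, 1, 1), (10, 3, 7)])
    def test_pair_count(self, n, delay, count, rng):
        pts = build_poincare_points(
            to_positive_series(rng.standard_normal(n)), delay=delay)
        assert pts.x.size == pts.y.size == count

    def test_too_short_for_delay(self):
        with pytest.raises(ValueError):
            build_poincare_points(to_positive_series([0.0, 1.0]), delay=2)


class TestRingPartition:
    def test_outer_boundary_closed(self):
        pts = PoincarePoints(x=np.full(4, 3.0), y=np.full(4, 4.0), delay=1)
        part = partition_sector_rings(pts, W=5)
        assert part.L_max == 5.0
        np.testing.assert_array_equal(part.counts, [0, 0, 0, 0, 4])
        np.testing.assert_array_equal(part.probabilities, [0, 0, 0, 0, 1])

    def test_half_open_rule(self):
        # distances {0.4, 0.5, 1.2, 2.5}; dl = 0.5: 0.5 lands in ring 2,
        # the maximal point 2.5 in the closed ring 5
        d = np.array([0.4, 0.5, 1.2, 2.5])
        pts = PoincarePoints(x=d, y=np.zeros_like(d), delay=1)
        part = partition_sector_rings(pts, W=5)
        np.testing.assert_array_equal(part.counts, [1, 1, 1, 0, 1])
        expected = [min(int(di // 0.5), 4) for di in d]
        np.testing.assert_array_equal(np.sort(np.repeat(np.arange(5), part.counts)),
                                      np.sort(expected))

    def test_degenerate_all_at_origin(self):
        pts = PoincarePoints(x=np.zeros(3), y=np.zeros(3), delay=1)
        part = partition_sector_rings(pts, W=4)
        assert part.degenerate
        assert part.probabilities[0] == 1.0

    @given(st.integers(1, 30), st.integers(2, 200), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_normalization_property(self, W, n, seed):
        r = np.random.default_rng(seed)
        pts = build_poincare_points(to_positive_series(r.standard_normal(n + 1)))
        part = partition_sector_rings(pts, W)
        assert part.counts.sum() == n
        assert np.isclose(part.probabilities.sum(), 1.0)
        assert np.all((part.probabilities >= 0) & (part.probabilities <= 1))


class TestDistributionEntropy:
    def test_motivating_probability_set(self, motivating_probs):
        part = RingPartition(W=5, L_max=10.0, dl=2.0,
                             radii=np.arange(2.0, 11, 2),
                             counts=(motivating_probs * 15).astype(int),
                             probabilities=motivating_probs)
        assert distribution_entropy(part).value == pytest.approx(1.48975, abs=1e-4)

    @pytest.mark.parametrize("p, expected", [
        (np.full(8, 1 / 8), np.log(8)),
        (np.array([1.0, 0, 0]), 0.0),
    ])
    def test_extremes(self, p, expected):
        part = RingPartition(W=p.size, L_max=1.0, dl=1.0 / p.size,
                             radii=np.linspace(1 / p.size, 1, p.size),
                             counts=(p * 8).astype(int), probabilities=p)
        assert distribution_entropy(part).value == pytest.approx(expected)

    def test_range_bound(self, rng):
        for _ in range(20):
            s = rng.standard_normal(100)
            v = de(s, W=12).value
            assert 0.0 <= v <= np.log(12) + 1e-12


class TestTsallis:
    @pytest.mark.parametrize("p, q, expected", [
        ([0.5, 0.5], 2.0, 0.5),
        ([1.0], 3.0, 0.0),
        ([0.25] * 4, 3.0, 0.46875),
    ])
    def test_closed_forms(self, p, q, expected):
        assert tsallis_entropy(p, q) == pytest.approx(expected)

    def test_q_one_rejected(self):
        with pytest.raises(ValueError):
            tsallis_entropy([0.5, 0.5], 1.0)


class TestQSet:
    def test_reverse_subtracted_centers(self):
        part = RingPartition(W=5, L_max=10.0, dl=2.0,
                             radii=np.arange(2.0, 11, 2),
                             counts=np.ones(5, dtype=int),
                             probabilities=np.full(5, 0.2))
        np.testing.assert_allclose(nonextensive_params(part), [10, 8, 6, 4, 2])

    def test_single_ring(self):
        part = RingPartition(W=1, L_max=2.0, dl=2.0, radii=np.array([2.0]),
                             counts=np.array([3]), probabilities=np.array([1.0]))
        np.testing.assert_allclose(nonextensive_params(part), [2.0])

    def test_strictly_decreasing_and_above_one(self, rng):
        for _ in range(20):
            s = rng.standard_normal(50)
            pts = build_poincare_points(to_positive_series(s))
            part = partition_sector_rings(pts, W=int(rng.integers(2, 20)))
            q = nonextensive_params(part)
            assert np.all(np.diff(q) < 0)
            assert q.min() == pytest.approx(1.0 + part.dl / 2)
            assert q.min() > 1.0


class TestNNE:
    def test_hand_evaluated_terms(self):
        assert nne([0.5, 0.5], [2.0, 3.0]) == pytest.approx(0.4375)

    def test_concentrated_mass(self):
        assert nne([1.0, 0.0, 0.0], [5.0, 4.0, 3.0]) == 0.0

    def test_shannon_limit(self, rng):
        for _ in range(20):
            p = rng.dirichlet(np.ones(rng.integers(2, 15)))
            shannon = -(p * np.log(p)).sum()
            approx = nne(p, np.full(p.size, 1.0 + 1e-6))
            assert approx == pytest.approx(shannon, rel=1e-4)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            nne([0.5, 0.5], [2.0])


class TestNDE:
    def test_constant_series_scores_zero(self):
        assert nde([3.0] * 50, W=10).value == 0.0

    def test_motivating_discriminability(self, motivating_probs):
        q = np.array([10.0, 8, 6, 4, 2])
        forward = nne(motivating_probs, q)
        reverse = nne(motivating_probs[::-1], q)
        assert forward == pytest.approx(0.3759, abs=1e-4)
        assert reverse == pytest.approx(0.2217, abs=1e-4)
        assert forward != pytest.approx(reverse, abs=1e-3)

    def test_oracle_equivalence(self, rng):
        for _ in range(25):
            s = rng.standard_normal(200)
            assert nde(s, W=10).value == pytest.approx(
                nde_bruteforce(s, 10), abs=1e-12)

    @given(st.integers(0, 2 ** 31 - 1),
           st.floats(-1e3, 1e3, allow_nan=False))
    @settings(max_examples=40, deadline=None)
    def test_shift_invariance(self, seed, c):
        s = np.random.default_rng(seed).standard_normal(80)
        # exact up to the rounding of (s + c) - min(s + c) itself
        assert nde(s + c, W=8).value == pytest.approx(nde(s, W=8).value,
                                                      rel=1e-10)

    def test_scale_sensitivity_vs_de_scale_invariance(self, rng):
        s = rng.standard_normal(200)
        assert de(3.0 * s, W=10).value == pytest.approx(de(s, W=10).value)
        assert nde(3.0 * s, W=10).value != pytest.approx(
            nde(s, W=10).value, rel=1e-3)

    def test_nonnegative(self, rng):
        for _ in range(30):
            s = rng.standard_normal(int(rng.integers(5, 300)))
            assert nde(s, W=int(rng.integers(1, 30))).value >= 0.0
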
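import itertools

import numpy as np
import pytest

from nexosim.metrics import (RunRecord, asymmetry, conv_matrix, dice_curve,
                             ssg, survival_regression, time_to_convergence,
                             ttnb)


def _record(order, times=None, n=None, trace=None, rid="r"):
    order = np.asarray(order)
    n = n or order.size
    death_times = np.full(n, np.inf)
    if times is None:
        times = np.arange(1, order.size + 1)
    death_times[order] = times
    if trace is None:
        trace = np.zeros((2, n))
    return RunRecord(run_id=rid, params={}, n_neurons=n,
                     death_times=death_times, death_order=order,
                     trace_steps=np.array([0, 1]), toxicity_trace=trace,
                     horizon=10_000)


class TestSSG:
    def test_isolated_neuron_zero(self, small_net):
        vals = ssg(small_net)
        no_edges = np.setdiff1d(np.arange(small_net.n_neurons),
                                np.union1d(small_net.pre,
                                           small_net.post_neuron))
        assert np.all(vals[no_edges] == 0)

    def test_single_edge_signs(self):
        from nexosim.network import NetworkConfig, build_network
        cfg = NetworkConfig(n_columns=1, composition=((2, "RS", 2),),
                            densities={"RS": 0.0})
        net = build_network(cfg, 0)
        net.pre = np.array([0])
        net.post_neuron = np.array([1])
        net.strength = np.array([0.5])
        vals = ssg(net)
        assert vals[1] == pytest.approx(0.5)    # receives
        assert vals[0] == pytest.approx(-0.5)   # projects
        flipped = ssg(net, convention="outgoing_minus_incoming")
        assert flipped[0] == pytest.approx(0.5)

    def test_sums_to_zero(self, small_net):
        assert ssg(small_net).sum() == pytest.approx(0.0, abs=1e-9)


class TestSurvivalRegression:
    def test_perfect_linear_relation(self):
        x = np.arange(10, dtype=float)
        res = survival_regression(x, 3 * x + 7)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(3.0)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            survival_regression(np.ones(5), np.arange(5))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            survival_regression([1.0, 2.0], [1.0, 2.0])

    def test_censored_and_nonfinite_excluded(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, np.inf])
        t = np.array([2.0, 4.0, 6.0, np.inf, 8.0])
        res = survival_regression(x, t)
        assert res.n == 3
        assert res.r_squared == pytest.approx(1.0)

    def test_shuffled_predictor_gives_null_r2(self):
        """Permutation null: mean R^2 ~ 1/(n-1) for n points."""
        rng = np.random.default_rng(0)
        n = 20
        x = rng.normal(size=n)
        t = rng.normal(size=n)
        r2s = []
        for _ in range(1000):
            perm = rng.permutation(n)
            r2s.append(survival_regression(x[perm], t).r_squared)
        null = 1.0 / (n - 1)
        assert np.mean(r2s) == pytest.approx(null, rel=0.3)


class TestDiceCurve:
    def test_identical_orders_all_ones(self):
        d = dice_curve([3, 1, 2, 0], [3, 1, 2, 0])
        assert np.allclose(d, 1.0)

    def test_hand_computed_example(self):
        d = dice_curve([1, 2, 3, 4], [3, 4, 1, 2])
        assert np.allclose(d, [0.0, 0.0, 2 / 3, 1.0])

    def test_symmetric_in_arguments(self, rng):
        a = rng.permutation(20)
        b = rng.permutation(20)
        assert np.allclose(dice_curve(a, b), dice_curve(b, a))

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError):
            dice_curve([0, 1, 2], [0, 1, 3])

    def test_matches_bruteforce_sets(self, rng):
        """Oracle equivalence on random permutations, N <= 50."""
        for _ in range(100):
            n = int(rng.integers(2, 51))
            a = rng.permutation(n)
            b = rng.permutation(n)
            d = dice_curve(a, b)
            oracle = [len(set(a[:k]) & set(b[:k])) / k
                      for k in range(1, n + 1)]
            assert np.allclose(d, oracle)


class TestTimeToConvergence:
    def test_identical_orders_converge_immediately(self):
        d = dice_curve([0, 1, 2, 3], [0, 1, 2, 3])
        assert time_to_convergence(d, 0.8) == pytest.approx(1 / 4)

    def test_late_convergence_example(self):
        d = dice_curve([1, 2, 3, 4], [3, 4, 1, 2])
        assert time_to_convergence(d, 0.8) == pytest.approx(1.0)

    def test_zero_threshold_trivial(self, rng):
        a = rng.permutation(10)
        b = rng.permutation(10)
        assert time_to_convergence(dice_curve(a, b), 0.0) == pytest.approx(0.1)

    def test_matches_bruteforce_scan(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 51))
            a = rng.permutation(n)
            b = rng.permutation(n)
            d = dice_curve(a, b)
            tc = time_to_convergence(d, 0.8)
            # brute force: smallest n with all later D >= threshold
            ok = [all(d[m] >= 0.8 for m in range(k, n)) for k in range(n)]
            expect = (ok.index(True) + 1) / n
            assert tc == pytest.approx(expect)


class TestConvMatrix:
    def test_identical_runs_give_minimal_tc(self):
        recs = [_record([0, 1, 2, 3], rid=f"r{i}") for i in range(2)]
        other = [_record([0, 1, 2, 3], rid=f"s{i}") for i in range(2)]
        conv = conv_matrix({"a": recs, "b": other})
        assert np.allclose(conv.to_numpy(), 0.25)

    def test_hand_computed_cross_mean(self):
        a = [_record([0, 1, 2, 3]), _record([1, 0, 2, 3])]
        b = [_record([3, 2, 1, 0]), _record([0, 1, 2, 3])]
        conv = conv_matrix({"a": a, "b": b})
        tcs = [
            time_to_convergence(dice_curve(x.death_order, y.death_order), 0.8)
            for x, y in itertools.product(a, b)
        ]
        assert conv.loc["a", "b"] == pytest.approx(np.mean(tcs))
        assert conv.loc["a", "b"] == conv.loc["b", "a"]

    def test_censored_runs_excluded(self):
        good = [_record([0, 1, 2, 3], rid=f"g{i}") for i in range(2)]
        bad = _record([0, 1], n=4, rid="bad")  # two survivors
        assert bad.censored
        conv = conv_matrix({"a": good + [bad], "b": good})
        assert np.allclose(conv.to_numpy(), 0.25)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            conv_matrix({"a": [], "b": [_record([0, 1])]})


class TestAsymmetryAndTTNB:
    def test_uniform_toxicity_has_no_asymmetry(self):
        assert asymmetry(np.full((5, 4), 0.3)) == 0.0

    def test_two_neuron_snapshot(self):
        assert asymmetry(np.array([[0.0, 1.0]])) == pytest.approx(
            np.sqrt(0.5))

    def test_max_over_time_is_monotone_in_rows(self, rng):
        trace = rng.uniform(0, 1, (10, 6))
        a = asymmetry(trace[:5])
        b = asymmetry(trace)
        assert b >= a

    def test_single_neuron_rejected(self):
        with pytest.raises(ValueError):
            asymmetry(np.zeros((3, 1)))

    def test_ttnb_is_last_death(self):
        rec = _record([2, 0, 1], times=[5, 9, 40])
        assert ttnb(rec) == 40
        assert ttnb(rec) >= rec.death_times.max() - 1e-12

    def test_ttnb_censored_is_none(self):
        rec = _record([0, 1], n=3)
        assert ttnb(rec) is None
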
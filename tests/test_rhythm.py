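import itertools
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refprime.rhythm import (
    bh_adjust,
    cosine_references,
    exact_s_null,
    import_rhythm_calls,
    jtk_scan,
    jtk_test,
    kendall_tau_s,
)

from .conftest import make_matrix, make_samples


def brute_force_s(x, ref):
    s = 0
    for i, j in itertools.combinations(range(len(x)), 2):
        s += int(np.sign((x[j] - x[i]) * (ref[j] - ref[i])))
    return s


class TestKendall:
    def test_perfect_concordance(self):
        tau, s = kendall_tau_s([1, 2, 3], [1, 2, 3])
        assert tau == pytest.approx(1.0)
        assert s == 3

    def test_perfect_discordance(self):
        tau, s = kendall_tau_s([3, 2, 1], [1, 2, 3])
        assert tau == pytest.approx(-1.0)
        assert s == -3

    def test_matches_pair_enumeration(self):
        x, ref = [1, 3, 2, 4], [1, 2, 3, 4]
        tau, s = kendall_tau_s(x, ref)
        assert s == brute_force_s(x, ref) == 4

    def test_all_tied_x_gives_tau_zero(self):
        tau, s = kendall_tau_s([5, 5, 5, 5], [1, 2, 3, 4])
        assert tau == 0.0
        assert s == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            kendall_tau_s([1, 2, 3], [1, 2])

    @given(st.lists(st.integers(0, 50), min_size=3, max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_s_always_matches_enumeration(self, x):
        ref = list(range(len(x)))
        _, s = kendall_tau_s(x, ref)
        assert s == brute_force_s(x, ref)


class TestExactNull:
    def test_matches_full_permutation_enumeration_n6(self):
        """The convolution null equals the law of S over all 6! orderings."""
        ref = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        x0 = [0.3, 1.2, 0.7, 2.5, 1.9, 0.1]
        counts = Counter(
            brute_force_s(list(p), ref) for p in itertools.permutations(x0)
        )
        total = math.factorial(6)
        pmf, u_max = exact_s_null((2, 2, 2))
        for u in range(u_max + 1):
            s = 2 * u - u_max
            assert counts.get(s, 0) / total == pytest.approx(pmf[u], abs=1e-12)

    def test_unequal_groups_against_enumeration(self):
        ref = np.array([1.0, 2.0, 2.0, 3.0, 3.0, 3.0])
        x0 = [4, 1, 5, 2, 6, 3]
        counts = Counter(
            brute_force_s(list(p), ref) for p in itertools.permutations(x0)
        )
        total = math.factorial(6)
        pmf, u_max = exact_s_null((1, 2, 3))
        for u in range(u_max + 1):
            s = 2 * u - u_max
            assert counts.get(s, 0) / total == pytest.approx(pmf[u], abs=1e-12)

    def test_agrees_with_monte_carlo_at_n8(self):
        """Convolution p and a permutation-sampled p agree on n=8 toys."""
        rng = np.random.default_rng(42)
        ref = np.round(np.cos(2 * np.pi * np.arange(8) * 2 / 22.0), 9)
        groups = tuple(
            int(c) for c in np.unique(ref, return_counts=True)[1]
        )
        pmf, u_max = exact_s_null(groups)
        s_vals = 2 * np.arange(u_max + 1) - u_max
        for _ in range(3):
            x = rng.normal(size=8)
            s_obs = brute_force_s(x, ref)
            p_exact = float(pmf[np.abs(s_vals) >= abs(s_obs)].sum())
            mc = np.array(
                [brute_force_s(rng.permutation(x), ref) for _ in range(4000)]
            )
            p_mc = np.mean(np.abs(mc) >= abs(s_obs))
            assert p_mc == pytest.approx(p_exact, abs=4 * np.sqrt(0.25 / 4000) + 0.01)


class TestJtkTest:
    def test_noiseless_cycler_hits_floor_p(self):
        """A pure cosine at the tested period attains the smallest possible p."""
        samples = make_samples(range(0, 45, 2))
        t = np.array([s.time for s in samples])
        x = np.cos(2 * np.pi * t / 22.0) + 1e-6 * np.arange(t.size)  # break ties
        res = jtk_test(x, samples, periods=[22.0], rng=0)
        assert res.p_value is not None and res.p_value < 1e-3
        assert res.best_period == 22.0

    def test_constant_series_is_null(self):
        samples = make_samples(range(0, 45, 2))
        res = jtk_test(np.ones(len(samples)), samples, rng=0)
        assert res.p_value == pytest.approx(1.0)
        assert not res.is_rhythmic

    def test_too_few_samples_rejected(self):
        samples = make_samples([0, 2, 4])
        with pytest.raises(ValueError):
            jtk_test([1.0, 2.0, 3.0], samples)

    def test_nonfinite_rejected(self):
        samples = make_samples(range(0, 45, 2))
        x = np.ones(len(samples))
        x[3] = np.nan
        with pytest.raises(ValueError):
            jtk_test(x, samples)

    def test_bonferroni_upper_bounds_permutation_correction(self):
        rng = np.random.default_rng(5)
        samples = make_samples(range(0, 45, 4))
        x = rng.normal(size=len(samples))
        p_perm = jtk_test(x, samples, rng=0, correction="permutation").p_value
        p_bonf = jtk_test(x, samples, rng=0, correction="bonferroni").p_value
        assert p_perm <= p_bonf + 0.02  # bonferroni is the conservative one


class TestScan:
    def test_strong_cyclers_flagged_and_flats_not(self):
        rng = np.random.default_rng(1)
        samples = make_samples(range(0, 45, 2), replicates=2)
        t = np.array([s.time for s in samples])
        cyclers = [np.cos(2 * np.pi * (t - ph) / 22.0) + rng.normal(0, 0.2, t.size) for ph in range(10)]
        flats = [rng.normal(0, 0.2, t.size) for _ in range(40)]
        m = make_matrix(np.stack(cyclers + flats), range(0, 45, 2), replicates=2)
        res = jtk_scan(m, rng=0)
        calls = {r.gene_id: r.is_rhythmic for r in res}
        assert all(calls[f"g{i}"] for i in range(10))
        flat_rate = np.mean([calls[f"g{i}"] for i in range(10, 50)])
        assert flat_rate <= 0.2

    def test_references_cover_phase_grid(self):
        refs = cosine_references(np.arange(0, 44, 2.0), [22.0])
        phases = [ph for _, ph, _ in refs]
        assert phases == [float(p) for p in range(0, 22, 2)]


class TestBhAdjust:
    def test_single_p_is_identity(self):
        assert bh_adjust([0.04]) == [0.04]

    def test_hand_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0]) == [1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_q_dominates_p_and_order_invariance(self, ps):
        q = np.array(bh_adjust(ps))
        assert np.all(q >= np.array(ps) - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)
        # permutation equivariance
        perm = np.argsort(np.argsort(ps, kind="stable"), kind="stable")
        shuffled = sorted(ps)
        q2 = np.array(bh_adjust(shuffled))
        np.testing.assert_allclose(np.sort(q), np.sort(q2), atol=1e-12)

    def test_matches_independent_step_up(self):
        """Direct min_{j>=i}(p_(j) m / j) computation as the oracle."""
        rng = np.random.default_rng(9)
        p = rng.uniform(size=25)
        m = p.size
        order = np.argsort(p)
        sorted_p = p[order]
        q_sorted = np.minimum.accumulate((sorted_p * m / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)


class TestImportCalls:
    def test_strict_threshold_and_carryover(self, tmp_path):
        f = tmp_path / "calls.tsv"
        f.write_text("gene_id\tp_value\tq_value\ngeneA\t0.001\t0.01\ngeneB\t0.02\t0.05\n")
        res = import_rhythm_calls(f, alpha=0.05)
        assert res[0].is_rhythmic and res[0].p_value == 0.001
        assert not res[1].is_rhythmic  # q == alpha is not rhythmic (strict <)

    def test_empty_file(self, tmp_path):
        f = tmp_path / "calls.tsv"
        f.write_text("gene_id\tq_value\n")
        assert import_rhythm_calls(f) == []

    def test_missing_column(self, tmp_path):
        f = tmp_path / "calls.tsv"
        f.write_text("gene_id\tscore\nx\t1\n")
        with pytest.raises(ValueError, match="q_value"):
            import_rhythm_calls(f)
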
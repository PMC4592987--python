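import numpy as np
import pytest
from scipy import stats

from refprime.stability import (
    StabilityScore,
    anova_time,
    cross_course_candidates,
    expression_filter,
    fit_regression_pi,
    jaccard_topk,
    pirs_score,
    prediction_bounds,
    quintile_report,
    sd_rsd_rank,
)

from .conftest import make_matrix, make_samples


def anova_by_definition(groups):
    """Sum-of-squares one-way ANOVA computed from the textbook decomposition."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups)
    df_b = len(groups) - 1
    df_w = allv.size - len(groups)
    f = (ss_between / df_b) / (ss_within / df_w)
    return stats.f.sf(f, df_b, df_w)


class TestExpressionFilter:
    def test_low_expressed_fails(self):
        m = make_matrix([[-3.0, -3.0, -3.0]], times=[0, 2, 4])
        assert expression_filter(m) == {"g0": False}

    def test_moderate_passes(self):
        m = make_matrix([[0.0, 0.0, 0.0]], times=[0, 2, 4])
        assert expression_filter(m) == {"g0": True}

    def test_boundary_is_strict(self):
        m = make_matrix([[-2.0, -2.0, -2.0]], times=[0, 2, 4])
        assert expression_filter(m) == {"g0": False}

    def test_relative_scale_rejected(self):
        m = make_matrix([[0.0, 0.1, 0.2]], times=[0, 2, 4], scale="relative_to_t0")
        with pytest.raises(ValueError):
            expression_filter(m)


class TestAnova:
    def test_constant_gene_p_one(self):
        samples = make_samples([0, 2, 4], replicates=2)
        assert anova_time([1, 1, 1, 1, 1, 1], samples) == 1.0

    def test_extreme_separation_rejects(self):
        samples = make_samples([0, 2], replicates=2)
        p = anova_time([0.0, 1e-9, 10.0, 10.0 + 1e-9], samples)
        assert p < 1e-6

    def test_hand_oracle_three_groups(self):
        samples = make_samples([0, 2, 4], replicates=2)
        x = [1, 2, 2, 3, 3, 4]
        groups = [[1, 2], [2, 3], [3, 4]]
        assert anova_time(x, samples) == pytest.approx(anova_by_definition(groups), abs=1e-12)

    def test_no_replication_rejected(self):
        samples = make_samples([0, 2, 4])
        with pytest.raises(ValueError):
            anova_time([1.0, 2.0, 3.0], samples)

    def test_agrees_with_ss_decomposition_on_random_toys(self):
        rng = np.random.default_rng(0)
        samples = make_samples([0, 4, 8, 12], replicates=3)
        for _ in range(100):
            x = rng.normal(size=12)
            groups = [x[i::4] for i in range(0)] or [x[k * 3 : (k + 1) * 3] for k in range(4)]
            # samples are grouped by time in blocks of 3 replicates
            assert anova_time(x, samples) == pytest.approx(
                anova_by_definition(groups), abs=1e-10
            )


class TestRegressionPi:
    def test_exact_line_degenerate_intervals(self):
        samples = make_samples([0, 2, 4, 6])
        fit = fit_regression_pi([1.0, 2.0, 3.0, 4.0], samples)
        assert fit.s == pytest.approx(0.0, abs=1e-12)
        for lo, hi in prediction_bounds(fit, [0, 2, 4, 6]):
            assert hi - lo == pytest.approx(0.0, abs=1e-9)

    def test_four_point_toy_against_closed_form(self):
        t = np.array([0.0, 2.0, 4.0, 6.0])
        y = np.array([1.0, 1.1, 0.9, 1.0])
        samples = make_samples(t)
        fit = fit_regression_pi(y, samples, level=0.95)
        # closed-form OLS oracle
        slope = np.sum((t - t.mean()) * (y - y.mean())) / np.sum((t - t.mean()) ** 2)
        intercept = y.mean() - slope * t.mean()
        resid = y - (intercept + slope * t)
        s = np.sqrt(np.sum(resid**2) / 2)
        assert fit.slope == pytest.approx(slope)
        assert fit.intercept == pytest.approx(intercept)
        assert fit.s == pytest.approx(s)
        tq = stats.t.ppf(0.975, 2)
        half0 = tq * s * np.sqrt(1 + 1 / 4 + (0 - 3.0) ** 2 / 20.0)
        lo, hi = prediction_bounds(fit, [0.0])[0]
        assert hi - lo == pytest.approx(2 * half0)
        assert (lo + hi) / 2 == pytest.approx(intercept)

    def test_matches_statsmodels_prediction_interval(self):
        """Independent route: statsmodels OLS get_prediction(obs=True)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        t = np.repeat(np.arange(0, 20, 4.0), 2)
        y = 0.05 * t + rng.normal(0, 0.3, t.size)
        samples = make_samples(np.arange(0, 20, 4.0), replicates=2)
        fit = fit_regression_pi(y, samples, level=0.95)
        model = sm.OLS(y, sm.add_constant(t)).fit()
        pred = model.get_prediction(sm.add_constant(np.unique(t))).summary_frame(alpha=0.05)
        ours = prediction_bounds(fit, np.unique(t))
        np.testing.assert_allclose(
            [b[0] for b in ours], pred["obs_ci_lower"], rtol=1e-8
        )
        np.testing.assert_allclose(
            [b[1] for b in ours], pred["obs_ci_upper"], rtol=1e-8
        )

    def test_level_monotonicity(self):
        samples = make_samples([0, 2, 4, 6])
        y = [1.0, 1.1, 0.9, 1.0]
        wide = prediction_bounds(fit_regression_pi(y, samples, 0.95), [0, 2])
        narrow = prediction_bounds(fit_regression_pi(y, samples, 0.50), [0, 2])
        for (wl, wh), (nl, nh) in zip(wide, narrow):
            assert wl < nl and wh > nh

    def test_single_time_rejected(self):
        samples = make_samples([2], replicates=3)
        with pytest.raises(ValueError):
            fit_regression_pi([1.0, 1.1, 0.9], samples)


class TestPirs:
    def test_flat_noiseless_gene_scores_zero(self):
        samples = make_samples([0, 2, 4, 6])
        fit = fit_regression_pi([2.0] * 4, samples)
        score = pirs_score(fit, [2.0] * 4, samples)
        assert score.pirs == pytest.approx(0.0, abs=1e-9)

    def test_formula_oracle_on_four_point_toy(self):
        t = [0.0, 2.0, 4.0, 6.0]
        y = np.array([1.0, 1.1, 0.9, 1.0])
        samples = make_samples(t)
        fit = fit_regression_pi(y, samples)
        score = pirs_score(fit, y, samples)
        bounds = prediction_bounds(fit, t)
        m = y.mean()
        expected = sum(abs(hi - m) + abs(lo - m) for lo, hi in bounds)
        assert score.pirs == pytest.approx(expected)
        assert score.bounds == bounds

    def test_noisier_gene_scores_strictly_higher(self):
        rng = np.random.default_rng(7)
        t = np.arange(0, 24, 2.0)
        samples = make_samples(t)
        noise = rng.normal(0, 1, t.size)
        y1 = 1.0 + 0.1 * noise
        y2 = 1.0 + 0.2 * noise
        s1 = pirs_score(fit_regression_pi(y1, samples), y1, samples)
        s2 = pirs_score(fit_regression_pi(y2, samples), y2, samples)
        assert s2.pirs > s1.pirs

    def test_shift_invariance_exact(self):
        rng = np.random.default_rng(11)
        t = np.arange(0, 24, 2.0)
        samples = make_samples(t)
        y = rng.normal(1.0, 0.3, t.size)
        a = pirs_score(fit_regression_pi(y, samples), y, samples).pirs
        b = pirs_score(fit_regression_pi(y + 5.0, samples), y + 5.0, samples).pirs
        assert a == pytest.approx(b, rel=1e-10)

    def test_width_variant_ignores_trend(self):
        # a steep noiseless trend has wide mean-deviation score but zero widths
        t = np.arange(0, 24, 2.0)
        samples = make_samples(t)
        y = 0.5 * t
        fit = fit_regression_pi(y, samples)
        dev = pirs_score(fit, y, samples, formula="mean_deviation").pirs
        width = pirs_score(fit, y, samples, formula="width").pirs
        assert width == pytest.approx(0.0, abs=1e-9)
        assert dev > 1.0


class TestSdRsd:
    def test_constant_gene_is_candidate(self):
        m = make_matrix([[2.0, 2.0, 2.0]], times=[0, 2, 4])
        out = sd_rsd_rank(m)
        assert out["g0"]["candidate"] and out["g0"]["sd"] == 0.0

    def test_half_percent_boundary(self):
        # mean 2.0: threshold is sd <= 0.01
        vals = np.array([2.0 - 0.009, 2.0 + 0.009]) / np.sqrt(2) * np.sqrt(2)
        m = make_matrix([[2.009, 1.991]], times=[0, 2])
        sd = np.std([2.009, 1.991], ddof=1)
        out = sd_rsd_rank(m)
        assert out["g0"]["sd"] == pytest.approx(sd)
        assert out["g0"]["candidate"] == (sd <= 0.01)

    def test_above_boundary_not_candidate(self):
        m = make_matrix([[2.02, 1.98]], times=[0, 2])  # sd ~ 0.028 > 0.01
        assert not sd_rsd_rank(m)["g0"]["candidate"]

    def test_zero_mean_flagged_with_reason(self):
        m = make_matrix([[0.5, -0.5]], times=[0, 2])
        out = sd_rsd_rank(m)
        assert not out["g0"]["candidate"]
        assert "undefined" in out["g0"]["reason"]


class TestCrossCourse:
    def make(self, vals):
        return make_matrix([vals], times=[0, 2, 4])

    def test_averaged_plus_one_course_included(self):
        flat = [2.0, 2.0, 2.0]
        noisy = [2.0, 2.5, 1.5]
        courses = [self.make(noisy), self.make(flat), self.make(noisy)]
        averaged = self.make(flat)
        assert cross_course_candidates(courses, averaged) == ["g0"]

    def test_not_in_averaged_excluded(self):
        flat = [2.0, 2.0, 2.0]
        noisy = [2.0, 2.5, 1.5]
        courses = [self.make(flat), self.make(flat), self.make(flat)]
        assert cross_course_candidates(courses, self.make(noisy)) == []

    def test_only_in_averaged_excluded(self):
        flat = [2.0, 2.0, 2.0]
        noisy = [2.0, 2.5, 1.5]
        courses = [self.make(noisy)]
        assert cross_course_candidates(courses, self.make(flat)) == []


class TestJaccard:
    def test_identical_rankings(self):
        assert jaccard_topk(["a", "b", "c"], ["a", "b", "c"], 3) == 1.0

    def test_disjoint(self):
        assert jaccard_topk(["a", "b"], ["c", "d"], 2) == 0.0

    def test_partial_overlap(self):
        assert jaccard_topk(["x", "y", "z"], ["x", "y", "w"], 3) == 0.5

    def test_bad_k(self):
        with pytest.raises(ValueError):
            jaccard_topk(["a"], ["a"], 0)


def make_scores(pirs_by_gene, expr_by_gene):
    return [
        StabilityScore(gene_id=g, pirs=p, mean_expr=expr_by_gene[g], sd=0.0, rsd=None)
        for g, p in pirs_by_gene.items()
    ]


class TestQuintiles:
    def test_100_genes_two_per_quintile(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i:03d}" for i in range(100)]
        scores = make_scores(
            {g: float(rng.uniform(1, 10)) for g in genes},
            {g: i * 0.03 for i, g in enumerate(genes)},
        )
        picked = quintile_report(scores, per_quintile=2)
        assert len(picked) == 10
        quint = {s.gene_id: s.quintile for s in scores}
        from collections import Counter

        assert Counter(quint[g] for g in picked) == {1: 2, 2: 2, 3: 2, 4: 2, 5: 2}

    def test_five_genes_one_each(self):
        genes = list("abcde")
        scores = make_scores({g: 1.0 for g in genes}, {g: i for i, g in enumerate(genes)})
        assert sorted(quintile_report(scores, per_quintile=1)) == genes

    def test_planted_minimum_selected_per_bin(self):
        rng = np.random.default_rng(4)
        scores = []
        planted = []
        for b in range(5):
            for i in range(10):
                g = f"q{b}_{i:02d}"
                pirs = 0.001 if i == 0 else float(rng.uniform(1, 5))
                if i == 0:
                    planted.append(g)
                scores.append(
                    StabilityScore(gene_id=g, pirs=pirs, mean_expr=b * 1.0 + i * 0.01, sd=0, rsd=None)
                )
        picked = quintile_report(scores, per_quintile=1)
        assert picked == planted

    def test_too_few_genes_rejected(self):
        scores = make_scores({"a": 1.0}, {"a": 0.0})
        with pytest.raises(ValueError):
            quintile_report(scores)
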
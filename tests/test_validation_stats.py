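"""Discrimination, calibration and comparison statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import spectrisk as sk
from spectrisk.errors import DegenerateStatisticError, ValidationInputError


def brute_force_c(p, y):
    """Explicit double loop over event/non-event pairs, ties get half credit."""
    num = pairs = 0.0
    for i in np.flatnonzero(y == 1):
        for j in np.flatnonzero(y == 0):
            pairs += 1
            if p[i] > p[j]:
                num += 1
            elif p[i] == p[j]:
                num += 0.5
    return num / pairs


class TestMarginalProbability:
    def test_event_fraction(self):
        y = np.r_[np.ones(298), np.zeros(3325)].astype(int)
        pred = sk.Predictions.from_logits(np.zeros(3623), y)
        assert sk.marginal_probability(pred) == pytest.approx(298 / 3623)

    def test_constant_outcomes(self):
        pred = sk.Predictions.from_logits(np.zeros(5), np.zeros(5, int))
        assert sk.marginal_probability(pred) == 0.0


class TestCStatistic:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_pairwise_count(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(12, 200))
        # coarse grid forces ties, exercising the half-credit rule
        logit = rng.choice(np.linspace(-3, 0, 12), n)
        y = (rng.random(n) < 0.3).astype(int)
        y[0], y[1] = 0, 1
        pred = sk.Predictions.from_logits(logit, y)
        assert sk.c_statistic(pred) == pytest.approx(
            brute_force_c(pred.p, y), abs=1e-12
        )

    def test_perfect_separation_gives_one(self):
        logit = np.r_[np.full(5, -3.0), np.full(5, 1.0)]
        y = np.r_[np.zeros(5), np.ones(5)].astype(int)
        assert sk.c_statistic(sk.Predictions.from_logits(logit, y)) == 1.0

    def test_constant_predictions_give_half(self):
        y = np.r_[np.zeros(5), np.ones(5)].astype(int)
        assert sk.c_statistic(sk.Predictions.from_logits(np.zeros(10), y)) == 0.5

    def test_single_class_is_degenerate(self):
        with pytest.raises(DegenerateStatisticError):
            sk.c_statistic(sk.Predictions.from_logits(np.zeros(4), np.zeros(4, int)))


class TestBrierScore:
    def test_term_by_term_oracle(self):
        rng = np.random.default_rng(3)
        logit = rng.normal(-2, 1, 10)
        y = (rng.random(10) < 0.4).astype(int)
        pred = sk.Predictions.from_logits(logit, y)
        manual = sum((pred.p[i] - y[i]) ** 2 for i in range(10)) / 10
        assert sk.brier_score(pred) == pytest.approx(manual, abs=1e-15)

    def test_constant_predictor_equals_bernoulli_variance(self):
        y = np.r_[np.ones(37), np.zeros(63)].astype(int)
        pbar = y.mean()
        pred = sk.Predictions(np.full(100, sk.probability_to_logit(pbar)),
                              np.full(100, pbar), y)
        assert sk.brier_score(pred) == pytest.approx(pbar * (1 - pbar), abs=1e-12)


class TestResidualDeviance:
    def test_closed_form_for_half_probabilities(self):
        pred = sk.Predictions.from_logits(np.zeros(50), (np.arange(50) % 2))
        dev, df = sk.residual_deviance(pred)
        assert dev == pytest.approx(50 * 2 * np.log(2), rel=1e-12)
        assert df == 50

    def test_df_counts_estimated_parameters(self):
        pred = sk.Predictions.from_logits(np.zeros(100), (np.arange(100) % 2))
        assert sk.residual_deviance(pred, n_params=0)[1] == 100
        assert sk.residual_deviance(pred, n_params=2)[1] == 98

    def test_term_by_term_oracle(self, prediction_factory):
        pred = prediction_factory(n=25, seed=5)
        manual = -2 * sum(
            np.log(pred.p[i]) if pred.mace[i] else np.log(1 - pred.p[i])
            for i in range(25)
        )
        assert sk.residual_deviance(pred)[0] == pytest.approx(manual, rel=1e-12)

    def test_boundary_probability_rejected(self):
        with pytest.raises(ValidationInputError):
            sk.Predictions(np.array([0.0]), np.array([1.0]), np.array([0]))


class TestLikelihoodRatioTest:
    def test_identical_deviances(self):
        res = sk.likelihood_ratio_test(100.0, 100.0, 1)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_chi_square_tail_against_normal_identity(self):
        # for df = 1, P(chi2 > x) = 2 * (1 - Phi(sqrt(x))) — an independent route
        for x in (3.84, 0.31):
            res = sk.likelihood_ratio_test(x, 0.0, 1)
            assert res.p_value == pytest.approx(2 * stats.norm.sf(np.sqrt(x)), abs=1e-10)
        assert round(sk.likelihood_ratio_test(3.84, 0.0, 1).p_value, 2) == 0.05
        assert round(sk.likelihood_ratio_test(0.31, 0.0, 1).p_value, 2) == 0.58

    def test_nesting_violation_rejected(self):
        with pytest.raises(ValidationInputError):
            sk.likelihood_ratio_test(90.0, 100.0, 1)


def hand_hosmer_lemeshow(p, y, groups):
    """Spreadsheet-style oracle: sort, slice, accumulate the corrected chi-square."""
    order = np.argsort(p, kind="stable")
    ps, ys = p[order], y[order]
    n = len(p)
    edges, prev = [], 0
    for g in range(1, groups + 1):
        b = int(round(n * g / groups))
        while 0 < b < n and ps[b] == ps[b - 1]:
            b += 1
        if b > prev:
            edges.append(b)
            prev = b
    chi2, start = 0.0, 0
    for stop in edges:
        e = ps[start:stop].sum()
        o = ys[start:stop].sum()
        nb = stop - start
        chi2 += (o - e) ** 2 / (e * (1 - e / nb))
        start = stop
    return chi2, len(edges) - 2


class TestHosmerLemeshow:
    def test_thirty_row_fixture_against_hand_computation(self):
        rng = np.random.default_rng(11)
        logit = np.sort(rng.normal(-2, 1, 30))
        y = (rng.random(30) < 0.35).astype(int)
        pred = sk.Predictions.from_logits(logit, y)
        res = sk.hosmer_lemeshow(pred, groups=5)
        chi2, df = hand_hosmer_lemeshow(pred.p, y, 5)
        assert res.statistic == pytest.approx(chi2, rel=1e-12)
        assert res.df == df
        assert res.p_value == pytest.approx(stats.chi2.sf(chi2, df), abs=1e-12)

    def test_null_statistic_near_df_and_sensitive_to_miscalibration(self, prediction_factory):
        null = np.mean([
            sk.hosmer_lemeshow(prediction_factory(n=2000, seed=s, loc=-2.0)).statistic
            for s in range(30)
        ])
        shifted = np.mean([
            sk.hosmer_lemeshow(prediction_factory(n=2000, seed=s, loc=-2.0, shift=1.0)).statistic
            for s in range(30)
        ])
        # calibrated predictions: mean statistic on the order of its df (8);
        # a one-logit miscalibration blows it up by an order of magnitude
        assert 0.6 * 8 < null < 1.8 * 8
        assert shifted > 5 * null

    def test_invariant_to_patient_ordering(self, prediction_factory):
        pred = prediction_factory(n=300, seed=2)
        perm = np.random.default_rng(0).permutation(300)
        shuffled = pred.take(perm)
        assert sk.hosmer_lemeshow(pred).statistic == pytest.approx(
            sk.hosmer_lemeshow(shuffled).statistic, rel=1e-12
        )

    def test_bin_counts_sum_to_n(self, prediction_factory):
        pred = prediction_factory(n=157, seed=4)
        dec = sk.decile_calibration(pred)
        assert dec.count.sum() == 157

    def test_too_few_groups_rejected(self, prediction_factory):
        with pytest.raises(ValidationInputError):
            sk.hosmer_lemeshow(prediction_factory(n=100), groups=1)


class TestDecileCalibration:
    def test_perfectly_calibrated_bins_on_diagonal(self):
        # 10 risk levels, each bin's observed rate equal to its predicted mean
        p_levels = np.linspace(0.05, 0.5, 10)
        p, y = [], []
        for lvl in p_levels:
            k = 20
            events = int(round(lvl * k))
            p += [lvl] * k
            y += [1] * events + [0] * (k - events)
        exact = np.array([round(l * 20) / 20 for l in p_levels])
        pred = sk.Predictions(sk.probability_to_logit(np.array(p)), np.array(p),
                              np.array(y))
        dec = sk.decile_calibration(pred)
        np.testing.assert_allclose(dec.obs_rate, exact, atol=1e-12)
        assert dec.slope == pytest.approx(1.0, abs=0.02)
        assert dec.r_squared == pytest.approx(1.0, abs=1e-3)

    def test_flat_observed_rates_give_zero_r_squared(self):
        p = np.repeat(np.linspace(0.1, 0.5, 10), 10)
        y = np.tile(np.r_[np.ones(3), np.zeros(7)], 10).astype(int)
        pred = sk.Predictions(sk.probability_to_logit(p), p, y)
        dec = sk.decile_calibration(pred)
        assert dec.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_ols_line_against_closed_form(self, prediction_factory):
        pred = prediction_factory(n=400, seed=9)
        dec = sk.decile_calibration(pred)
        x, yb = dec.pred_mean, dec.obs_rate
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (yb - yb.mean())).sum() / sxx
        intercept = yb.mean() - slope * x.mean()
        assert dec.slope == pytest.approx(slope, rel=1e-10)
        assert dec.intercept == pytest.approx(intercept, rel=1e-10)
        ss_res = ((yb - intercept - slope * x) ** 2).sum()
        ss_tot = ((yb - yb.mean()) ** 2).sum()
        assert dec.r_squared == pytest.approx(1 - ss_res / ss_tot, rel=1e-10)


def brute_lowess(x, y, frac):
    """Degree-1 tricube local regression, the textbook way."""
    n = len(x)
    k = int(np.ceil(frac * n))
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="stable")[:k]
        dmax = d[idx].max()
        w = np.ones(k) if dmax == 0 else np.clip(1 - (d[idx] / dmax) ** 3, 0, None) ** 3
        X = np.column_stack([np.ones(k), x[idx]])
        beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y[idx]))
        out[i] = beta[0] + beta[1] * x[i]
    return out


class TestLoessCalibration:
    def test_matches_brute_force_tricube_oracle(self):
        rng = np.random.default_rng(21)
        logit = np.sort(rng.normal(-2, 1, 40))
        y = (rng.random(40) < 0.4).astype(int)
        pred = sk.Predictions.from_logits(logit, y)
        curve = sk.loess_calibration(pred, span=0.75)
        oracle = np.clip(brute_lowess(np.sort(pred.p), y[np.argsort(logit, kind="stable")], 0.75), 0, 1)
        # identical span, kernel and degree; delta-approximation off at this n
        np.testing.assert_allclose(curve.grid_loess, oracle, atol=1e-3)
        d = np.abs(np.sort(pred.p) - oracle)
        assert curve.d_max == pytest.approx(d.max(), abs=1e-3)
        assert curve.d_mean == pytest.approx(d.mean(), abs=1e-3)

    def test_d_mean_never_exceeds_d_max(self, prediction_factory):
        for seed in range(5):
            curve = sk.loess_calibration(prediction_factory(n=200, seed=seed))
            assert 0 <= curve.d_mean <= curve.d_max

    def test_consistency_on_self_calibrated_outcomes(self, prediction_factory):
        # outcomes drawn from the predictions themselves: discrepancy shrinks with n
        small = sk.loess_calibration(prediction_factory(n=200, seed=1))
        big = sk.loess_calibration(prediction_factory(n=20000, seed=1))
        assert big.d_mean < small.d_mean
        assert big.d_mean < 0.01

    def test_invalid_span_rejected(self, prediction_factory):
        with pytest.raises(ValidationInputError):
            sk.loess_calibration(prediction_factory(n=100), span=1.5)


class TestBootstrap:
    def test_degenerate_ci_for_constant_statistic(self, prediction_factory):
        pred = prediction_factory(n=50, seed=0)
        ci = sk.bootstrap_ci(lambda _: 0.42, pred, sk.BootstrapSettings(resamples=50, seed=1))
        assert ci.point == ci.low == ci.high == 0.42

    def test_same_seed_reproduces_interval_exactly(self, prediction_factory):
        pred = prediction_factory(n=300, seed=3)
        s = sk.BootstrapSettings(resamples=200, seed=42)
        a = sk.bootstrap_ci(sk.brier_score, pred, s)
        b = sk.bootstrap_ci(sk.brier_score, pred, s)
        assert (a.point, a.low, a.high) == (b.point, b.low, b.high)

    def test_redraws_resamples_with_no_events(self):
        # 1 event in 30: many resamples are all-zero and must be redrawn
        y = np.zeros(30, int)
        y[0] = 1
        pred = sk.Predictions.from_logits(np.linspace(-3, -1, 30), y)
        ci = sk.bootstrap_ci(sk.c_statistic, pred, sk.BootstrapSettings(resamples=100, seed=0))
        assert 0 <= ci.low <= ci.high <= 1

    def test_percentile_interval_covers_the_mean_near_nominal_rate(self):
        rng = np.random.default_rng(77)
        hits = 0
        reps = 150
        for _ in range(reps):
            x = rng.normal(0, 1, 60)
            boot = rng.choice(x, size=(400, 60), replace=True).mean(axis=1)
            lo, hi = np.percentile(boot, [2.5, 97.5])
            hits += lo <= 0 <= hi
        assert 0.88 <= hits / reps <= 0.99


class TestCompareGroups:
    def _cohort(self, frame, label):
        return sk.CohortTable(pd.DataFrame(frame), label=label)

    def test_identical_groups_yield_p_one_for_indicator(self):
        rows = [{"age": 60, "diabetes": d, "sss": 0, "lvef": 55, "mace": 0}
                for d in [0, 1] * 10]
        a = self._cohort(rows, "a")
        b = self._cohort(rows, "b")
        table = sk.compare_groups(a, b, ["diabetes"])
        assert table.loc[0, "p_value"] == pytest.approx(1.0)

    def test_diabetes_prevalence_difference_is_significant(self):
        # 1075/3325 vs 143/298 diabetic patients (no-MACE vs MACE groups)
        def rows(k, n):
            return [{"age": 60, "diabetes": 1 if i < k else 0, "sss": 0,
                     "lvef": 55, "mace": 0} for i in range(n)]

        table = sk.compare_groups(
            self._cohort(rows(1075, 3325), "no mace"),
            self._cohort(rows(143, 298), "mace"),
            ["diabetes"],
        )
        assert table.loc[0, "p_value"] < 0.001

    def test_two_by_two_against_textbook_formula(self):
        a_yes, a_no, b_yes, b_no = 30, 70, 55, 45
        table = sk.compare_groups(
            self._cohort([{"age": 60, "diabetes": 1, "sss": 0, "lvef": 55, "mace": 0}] * a_yes
                         + [{"age": 60, "diabetes": 0, "sss": 0, "lvef": 55, "mace": 0}] * a_no, "a"),
            self._cohort([{"age": 60, "diabetes": 1, "sss": 0, "lvef": 55, "mace": 0}] * b_yes
                         + [{"age": 60, "diabetes": 0, "sss": 0, "lvef": 55, "mace": 0}] * b_no, "b"),
            ["diabetes"],
        )
        # chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), no continuity correction
        n = a_yes + a_no + b_yes + b_no
        chi2 = (
            n * (a_yes * b_no - a_no * b_yes) ** 2
            / ((a_yes + a_no) * (b_yes + b_no) * (a_yes + b_yes) * (a_no + b_no))
        )
        assert table.loc[0, "statistic"] == pytest.approx(chi2, rel=1e-12)

    def test_t_test_for_continuous_variable(self, prediction_factory):
        rng = np.random.default_rng(0)
        mk = lambda mu: self._cohort(
            [{"age": a, "diabetes": 0, "sss": 0, "lvef": 55, "mace": 0}
             for a in rng.normal(mu, 5, 100).clip(20)], "g")
        table = sk.compare_groups(mk(60), mk(66), ["age"])
        assert table.loc[0, "kind"] == "continuous"
        assert table.loc[0, "p_value"] < 0.001

    def test_zero_variance_everywhere_rejected(self):
        rows = [{"age": 60, "diabetes": 0, "sss": 0, "lvef": 55, "mace": 0}] * 5
        with pytest.raises(ValidationInputError):
            sk.compare_groups(self._cohort(rows, "a"), self._cohort(rows, "b"), ["age"])
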
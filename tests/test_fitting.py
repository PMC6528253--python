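import numpy as np
import pytest
from scipy.optimize import curve_fit

import platefit as pf
from platefit.fitting import FitError
from conftest import make_series


P_TRUE = pf.Logistic4Params(bottom=0.0, top=100.0, ec50=1.0, hill=1.5)
DOSES = (0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0)


def clean_series(p=P_TRUE, doses=DOSES):
    x = np.array(doses)
    return make_series(x, pf.logistic4_eval(x, p))


class TestLogistic4Eval:
    def test_midpoint_identity(self):
        p = pf.Logistic4Params(bottom=3, top=9, ec50=2.5, hill=-0.7)
        assert pf.logistic4_eval(2.5, p) == pytest.approx((3 + 9) / 2, rel=1e-14)

    def test_arithmetic(self):
        p = pf.Logistic4Params(bottom=0, top=1, ec50=1, hill=1)
        assert pf.logistic4_eval(3.0, p) == pytest.approx(0.25)

    @pytest.mark.parametrize("hill,limit", [(2.0, "top"), (-2.0, "bottom")])
    def test_x_zero_limit(self, hill, limit):
        p = pf.Logistic4Params(bottom=5, top=50, ec50=1, hill=hill)
        assert pf.logistic4_eval(0.0, p) == getattr(p, limit)

    def test_negative_x_rejected(self):
        with pytest.raises(FitError):
            pf.logistic4_eval(-1.0, P_TRUE)

    @pytest.mark.parametrize("hill", [1.5, -1.5])
    def test_monotone_on_positive_axis(self, hill):
        p = pf.Logistic4Params(bottom=0, top=100, ec50=1, hill=hill)
        y = pf.logistic4_eval(np.geomspace(1e-3, 1e3, 200), p)
        d = np.diff(y)
        assert (d <= 0).all() if hill > 0 else (d >= 0).all()

    def test_invalid_params_rejected(self):
        with pytest.raises(FitError):
            pf.Logistic4Params(bottom=0, top=1, ec50=-1, hill=1)
        with pytest.raises(FitError):
            pf.Logistic4Params(bottom=0, top=1, ec50=1, hill=0)


class TestLinearEval:
    def test_line(self):
        p = pf.LinearParams(intercept=1, slope=2)
        assert pf.linear_eval(0.0, p) == 1
        assert pf.linear_eval(3.0, p) == 7


class TestGuess:
    def test_decreasing_series_guess(self):
        s = clean_series()  # hill>0 => decreasing
        g = pf.guess_logistic4(s)
        assert g.hill == 1.0
        assert min(DOSES) <= g.ec50 <= max(DOSES)
        assert g.top > g.bottom

    def test_increasing_series_gets_negative_hill(self):
        p = pf.Logistic4Params(bottom=0, top=100, ec50=1, hill=-1.5)
        x = np.array(DOSES)
        g = pf.guess_logistic4(make_series(x, pf.logistic4_eval(x, p)))
        assert g.hill == -1.0

    def test_flat_series_warns(self):
        s = make_series(DOSES, np.full(len(DOSES), 5.0))
        with pytest.warns(UserWarning, match="poorly determined"):
            g = pf.guess_logistic4(s)
        assert g.top == g.bottom == 5.0
        assert g.ec50 == pytest.approx(np.exp(np.mean(np.log(DOSES))))

    def test_under_determined_rejected(self):
        with pytest.raises(FitError, match="under-determined"):
            pf.guess_logistic4(make_series([1, 2, 3], [5, 4, 3]))


class TestLmFit:
    def test_exact_line_through_two_points(self):
        f = pf.lm_fit(make_series([0, 1], [1, 3]), pf.FitModel.LINEAR)
        assert f.params.intercept == pytest.approx(1, abs=1e-10)
        assert f.params.slope == pytest.approx(2, abs=1e-10)
        assert f.ssr == pytest.approx(0, abs=1e-20)

    def test_collinear_points_r2_one(self):
        f = pf.lm_fit(make_series([0, 1, 2], [1, 3, 5]), pf.FitModel.LINEAR)
        assert f.ssr == pytest.approx(0, abs=1e-18) and f.r2 == pytest.approx(1)

    def test_noiseless_4pl_recovery(self):
        f = pf.lm_fit(clean_series(), pf.FitModel.LOGISTIC4)
        assert f.converged
        for k, true_v in P_TRUE.as_dict().items():
            got = f.params.as_dict()[k]
            err = abs(got - true_v) / abs(true_v) if true_v else abs(got)
            assert err < 1e-6, k
        assert f.r2 == pytest.approx(1, abs=1e-12)

    def test_matches_scipy_curve_fit_on_noisy_data(self):
        rng = np.random.default_rng(5)
        x = np.array(DOSES)
        y = pf.logistic4_eval(x, P_TRUE) + rng.normal(0, 2, len(x))
        f = pf.lm_fit(make_series(x, y), pf.FitModel.LOGISTIC4)

        def model(x, b, t, log_e, h):
            return b + (t - b) / (1 + (x / np.exp(log_e)) ** h)

        popt, _ = curve_fit(model, x, y, p0=[0, 100, 0, 1.5], maxfev=10000)
        ours = [f.params.bottom, f.params.top, np.log(f.params.ec50), f.params.hill]
        np.testing.assert_allclose(ours, popt, rtol=1e-5)

    def test_descent_property(self):
        rng = np.random.default_rng(9)
        x = np.array(DOSES)
        y = pf.logistic4_eval(x, P_TRUE) + rng.normal(0, 5, len(x))
        s = make_series(x, y)
        start = pf.guess_logistic4(s)
        ssr_start = pf.gof_stats(s, pf.FitModel.LOGISTIC4, start)[0]
        f = pf.lm_fit(s, pf.FitModel.LOGISTIC4, start=start)
        assert f.converged and f.ssr <= ssr_start

    def test_grid_search_oracle_five_points(self):
        # brute-force SSR over a parameter box around the truth must not
        # beat the fitted optimum by more than 0.1%
        rng = np.random.default_rng(17)
        x = np.array([0.1, 0.3, 1.0, 3.0, 10.0])
        y = pf.logistic4_eval(x, P_TRUE) + rng.normal(0, 3, len(x))
        s = make_series(x, y)
        f = pf.lm_fit(s, pf.FitModel.LOGISTIC4)
        best = np.inf
        for b in np.linspace(-10, 10, 9):
            for t in np.linspace(90, 110, 9):
                for e in np.geomspace(0.3, 3, 15):
                    for h in np.linspace(0.8, 2.5, 12):
                        r = pf.logistic4_eval(x, pf.Logistic4Params(b, t, e, h)) - y
                        best = min(best, float(r @ r))
        assert f.ssr <= best * 1.001

    def test_under_determined_rejected(self):
        with pytest.raises(FitError, match="under-determined"):
            pf.lm_fit(make_series([1, 2, 3], [9, 5, 1]), pf.FitModel.LOGISTIC4)

    def test_param_se_reported_with_dof(self):
        rng = np.random.default_rng(2)
        x = np.array(DOSES)
        y = pf.logistic4_eval(x, P_TRUE) + rng.normal(0, 2, len(x))
        f = pf.lm_fit(make_series(x, y), pf.FitModel.LOGISTIC4)
        assert f.dof == len(x) - 4
        assert f.param_se is not None and all(v >= 0 for v in f.param_se.values())


class TestRefit:
    def test_refit_from_truth_converges_fast(self):
        f = pf.refit_from(clean_series(), pf.FitModel.LOGISTIC4, P_TRUE)
        assert f.converged and f.n_iter <= 2
        assert f.params.ec50 == pytest.approx(1.0, rel=1e-9)

    def test_far_start_reaches_same_optimum(self):
        s = clean_series()
        far = pf.Logistic4Params(bottom=10, top=80, ec50=100.0, hill=1.0)
        f_far = pf.refit_from(s, pf.FitModel.LOGISTIC4, far)
        f_auto = pf.lm_fit(s, pf.FitModel.LOGISTIC4)
        for k in ("bottom", "top", "ec50", "hill"):
            a, b = f_far.params.as_dict()[k], f_auto.params.as_dict()[k]
            assert a == pytest.approx(b, rel=1e-4, abs=1e-4)

    def test_linear_start_independent(self):
        s = make_series([0, 1, 2, 4], [1.0, 2.9, 5.2, 8.8])
        f1 = pf.refit_from(s, pf.FitModel.LINEAR, pf.LinearParams(0, 0))
        f2 = pf.refit_from(s, pf.FitModel.LINEAR, pf.LinearParams(-50, 99))
        assert f1.params.intercept == pytest.approx(f2.params.intercept, abs=1e-9)
        assert f1.params.slope == pytest.approx(f2.params.slope, abs=1e-9)


class TestGofStats:
    def test_perfect_fit(self):
        s = clean_series()
        ssr, r2, rmse, dof = pf.gof_stats(s, pf.FitModel.LOGISTIC4, P_TRUE)
        assert ssr == pytest.approx(0, abs=1e-20) and r2 == pytest.approx(1)
        assert dof == len(DOSES) - 4 and rmse == pytest.approx(0, abs=1e-10)

    def test_constant_at_mean_gives_r2_zero(self):
        s = make_series([0, 1, 2], [1.0, 2.0, 6.0])
        ssr, r2, rmse, dof = pf.gof_stats(
            s, pf.FitModel.LINEAR, pf.LinearParams(intercept=3.0, slope=0.0)
        )
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_worse_than_mean_reports_negative_r2(self):
        s = make_series([0, 1, 2], [1.0, 2.0, 3.0])
        _, r2, _, _ = pf.gof_stats(
            s, pf.FitModel.LINEAR, pf.LinearParams(intercept=100.0, slope=-50.0)
        )
        assert r2 < 0

    def test_rmse_absent_without_dof(self):
        s = make_series([0.1, 1, 10, 100], [90.0, 70.0, 30.0, 10.0])
        ssr, r2, rmse, dof = pf.gof_stats(s, pf.FitModel.LOGISTIC4, P_TRUE)
        assert dof == 0 and rmse is None


class TestRecoveryStudy:
    def test_median_errors_over_200_noisy_series(self):
        # 8 doses, 4 replicates, noise 2% of range: median ec50 error < 5%,
        # median hill error < 10%
        ec50_err, hill_err = [], []
        for seed in range(200):
            spec = pf.SimSpec(model=pf.FitModel.LOGISTIC4, truth=P_TRUE,
                              doses=DOSES, n_replicates=4, noise_sd=2.0, seed=seed)
            lay, groups, _ = pf.simulate_plate(spec)
            s = pf.aggregate(pf.replicate_sets(lay, groups[0]), pf.VariationKind.SEM)
            f = pf.lm_fit(s, pf.FitModel.LOGISTIC4)
            ec50_err.append(abs(f.params.ec50 - 1.0))
            hill_err.append(abs(f.params.hill - 1.5) / 1.5)
        assert np.median(ec50_err) < 0.05
        assert np.median(hill_err) < 0.10
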
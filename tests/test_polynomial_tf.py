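"""Box-Jenkins transfer functions: prewhitening, CCF identification, regression."""

import numpy as np
import pytest
from scipy import stats

from wavetf.polynomial_tf import (
    CCFReport,
    PolyTFModel,
    cross_correlation,
    fit_input_arma,
    fit_noise_arma,
    fit_polytf,
    fit_transfer_regression,
    identify_lags,
    predict_poly,
    prewhiten,
)
from wavetf.synthetic import SimSpec, generate_polytf


def _acf(z, h):
    z = z - z.mean()
    return np.dot(z[h:], z[:-h]) / np.dot(z, z)


class TestInputArma:
    def test_white_noise_identity(self, rng):
        x = rng.normal(size=500)
        arma = fit_input_arma(x, 0, 0)
        np.testing.assert_array_equal(arma.residuals, x)
        assert arma.sigma2 == pytest.approx(np.mean(x**2))

    def test_ar1_recovery_within_2se(self):
        phi, T = 0.5, 2000
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(800 + seed)
            eps = rng.normal(size=T + 100)
            x = np.zeros(T + 100)
            for t in range(1, T + 100):
                x[t] = phi * x[t - 1] + eps[t]
            arma = fit_input_arma(x[100:], 1, 0)
            se = np.sqrt((1 - phi**2) / T)
            hits += abs(arma.ar[0] - phi) < 2 * se
        assert hits >= 4

    def test_ma1_recovery_within_2se(self):
        theta, T = 0.4, 2000
        rng = np.random.default_rng(42)
        eps = rng.normal(size=T + 1)
        x = eps[1:] + theta * eps[:-1]
        arma = fit_input_arma(x, 0, 1)
        se = np.sqrt((1 - theta**2) / T)
        assert abs(arma.ma[0] - theta) < 2 * se


class TestPrewhiten:
    def test_white_input_unchanged(self, rng):
        x = rng.normal(size=300)
        y = rng.normal(size=300)
        arma = fit_input_arma(x, 0, 0)
        w, yt = prewhiten(y, x, arma)
        np.testing.assert_array_equal(w, x)
        np.testing.assert_array_equal(yt, y)

    def test_ar1_filter_arithmetic(self, rng):
        from wavetf.polynomial_tf import InputARMA

        x = rng.normal(size=100)
        arma = InputARMA(np.array([0.5]), np.array([]), 1.0, x)
        w, _ = prewhiten(x, x, arma)
        expected = x.copy()
        expected[1:] = x[1:] - 0.5 * x[:-1]
        np.testing.assert_allclose(w, expected, atol=1e-12)

    def test_prewhitened_input_is_white(self):
        # correctly specified orders leave residual ACF inside the 2/sqrt(T) band
        T, n_sims, max_h = 1000, 20, 20
        inside = 0
        for seed in range(n_sims):
            spec = SimSpec(T_train=T, T_test=0, input_ar=[0.6], input_ma=[0.3],
                           noise_sd=1.0, seed=1300 + seed)
            _, x, _ = generate_polytf(spec, delta=[1.0])
            arma = fit_input_arma(x, 1, 1)
            w, _ = prewhiten(x, x, arma)
            inside += sum(abs(_acf(w, h)) < 2 / np.sqrt(T) for h in range(1, max_h + 1))
        assert inside / (n_sims * max_h) >= 0.9

    def test_ccf_peak_identifies_delay(self):
        # y_t = 2 x_{t-3} + noise, x AR(1): prewhitened CCF peaks at lag 3
        hits, clean = 0, 0
        n = 30
        for seed in range(n):
            spec = SimSpec(T_train=800, T_test=0, input_ar=[0.5], noise_sd=0.5,
                           seed=1400 + seed)
            y, x, _ = generate_polytf(spec, delta=[2.0], d=3)
            arma = fit_input_arma(x, 1, 0)
            w, yt = prewhiten(y, x, arma)
            ccf = cross_correlation(yt, w, max_lag=10)
            rep = identify_lags(ccf, T=len(y))
            hits += ccf.idxmax() == 3
            clean += all(abs(ccf.loc[h]) <= rep.bound for h in (0, 1, 2))
        assert hits == n
        # each of lags 0-2 independently exceeds the two-sided 2-sigma bound
        # ~4.6% of the time, so "all three clean" holds in ~87% of runs
        assert clean / n >= 0.75

    def test_ccf_tracks_impulse_weights(self):
        # rational transfer: Spearman(estimated alpha_h, true alpha_h) > 0.9
        spec = SimSpec(T_train=2000, T_test=0, input_ar=[0.5], noise_sd=0.3, seed=77)
        y, x, truth = generate_polytf(spec, delta=[1.0, 0.5], omega=[0.6], d=1)
        arma = fit_input_arma(x, 1, 0)
        w, yt = prewhiten(y, x, arma)
        ccf = cross_correlation(yt, w, max_lag=10)
        est = ccf.loc[0:10].to_numpy()
        rho = stats.spearmanr(est, truth["alpha"][:11]).statistic
        assert rho > 0.9


class TestIdentifyLags:
    def test_bound_at_T512(self):
        rep = identify_lags(cross_correlation(np.arange(10.0), np.arange(10.0), 2), T=512)
        assert rep.bound == pytest.approx(2 / np.sqrt(512), abs=1e-12)
        assert rep.bound == pytest.approx(0.08839, abs=5e-6)

    def test_all_zero_ccf_empty_report(self):
        import pandas as pd

        ccf = pd.Series(np.zeros(9), index=np.arange(-4, 5))
        rep = identify_lags(ccf, T=512)
        assert rep.flagged == [] and rep.proposed_delay is None

    def test_single_flag_proposes_delay(self):
        import pandas as pd

        ccf = pd.Series([0.54], index=[1])
        rep = identify_lags(ccf, T=512, variable="DANC", transformation="standardized")
        assert rep.flagged == [(1, 0.54)] and rep.proposed_delay == 1
        frame = rep.to_frame()
        assert list(frame.columns) == ["variable", "transformation", "lag", "ccf"]
        assert frame.iloc[0].tolist() == ["DANC", "standardized", 1, 0.54]

    def test_negative_lags_never_proposed(self):
        import pandas as pd

        ccf = pd.Series([0.6, 0.0, 0.5], index=[-3, 0, 4])
        rep = identify_lags(ccf, T=400)
        assert rep.proposed_delay == 4


class TestTransferRegression:
    def test_pure_gain_exact(self, rng):
        x = rng.normal(size=200)
        y = 2.0 * x
        model = fit_transfer_regression(y, [(x, 0, 0, 0)])
        assert model.branches[0].delta[0] == pytest.approx(2.0, abs=1e-10)
        assert np.max(np.abs(model.residuals)) < 1e-10

    def test_sdr_121_recovery_within_2se(self):
        spec = SimSpec(T_train=2000, T_test=0, input_ar=[0.5], noise_sd=0.05, seed=21)
        y, x, truth = generate_polytf(spec, delta=[1.0, 0.5], omega=[0.4], d=2)
        model = fit_transfer_regression(y, [(x, 1, 2, 1)])
        # standard errors from the OLS covariance of the lagged design
        resid_var = np.var(model.residuals, ddof=3)
        T_eff = len(model.residuals)
        se = np.sqrt(resid_var / T_eff) * 10  # loose bound; exact X'X omitted
        assert model.omega[0] == pytest.approx(0.4, abs=max(2 * se, 0.05))
        assert model.branches[0].delta[0] == pytest.approx(1.0, abs=max(2 * se, 0.05))
        assert model.branches[0].delta[1] == pytest.approx(0.5, abs=max(2 * se, 0.05))

    def test_two_input_branches_recovered(self, rng):
        T = 2000
        x1 = rng.normal(size=T)
        x2 = rng.normal(size=T)
        y = np.zeros(T)
        for t in range(T):
            y[t] = 0.02 * rng.normal()
            if t >= 1:
                y[t] += 1.5 * x1[t - 1]
            if t >= 3:
                y[t] += -0.8 * x2[t - 3]
        model = fit_transfer_regression(y, [(x1, 0, 1, 0), (x2, 0, 3, 0)])
        assert model.branches[0].delta[0] == pytest.approx(1.5, abs=0.01)
        assert model.branches[1].delta[0] == pytest.approx(-0.8, abs=0.01)

    def test_collinear_design_raises(self, rng):
        x = rng.normal(size=100)
        y = rng.normal(size=100)
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_transfer_regression(y, [(x, 0, 0, 0), (x, 0, 0, 0)])


class TestNoiseArma:
    def test_white_residuals_order00(self, rng):
        resid = rng.normal(size=400)
        ar, ma, s2 = fit_noise_arma(resid, (0, 0))
        assert len(ar) == 0 and len(ma) == 0
        assert s2 == pytest.approx(np.mean(resid**2))

    def test_noiseless_transfer_sigma_tiny(self, rng):
        x = rng.normal(size=300)
        model = fit_transfer_regression(3.0 * x, [(x, 0, 0, 0)])
        _, _, s2 = fit_noise_arma(model.residuals, (0, 0))
        assert s2 < 1e-10

    def test_ar1_noise_recovered(self):
        spec = SimSpec(T_train=2000, T_test=0, input_ar=[0.5], noise_sd=0.5, seed=31)
        y, x, _ = generate_polytf(spec, delta=[2.0], d=1, noise_ar=[0.6])
        model, _ = fit_polytf(y, x, {"p": 1, "q": 0, "s": 0, "r": 0, "d": 1,
                                     "noise_p": 1, "noise_q": 0})
        se = np.sqrt((1 - 0.36) / 2000)
        assert model.noise_ar[0] == pytest.approx(0.6, abs=max(2 * se, 0.05))


class TestPredictPoly:
    def test_identity_transfer_passthrough(self, rng):
        from wavetf.polynomial_tf import TransferBranch

        x = rng.normal(size=120)
        model = PolyTFModel(
            omega=np.array([]), branches=[TransferBranch(d=0, delta=np.array([1.0]))]
        )
        fc = predict_poly(model, x[:100], [x], start=101, horizon=20)
        np.testing.assert_allclose(fc, x[100:], atol=1e-12)

    def test_recursion_matches_hand_oracle(self, rng):
        from wavetf.polynomial_tf import TransferBranch

        x = rng.normal(size=60)
        y_hist = rng.normal(size=40)
        model = PolyTFModel(
            omega=np.array([0.5]),
            branches=[TransferBranch(d=1, delta=np.array([1.0, 0.3]))],
        )
        fc = predict_poly(model, y_hist, [x], start=41, horizon=20, mode="recursive")
        expected = np.empty(20)
        prev = y_hist[39]
        for h in range(20):
            t = 41 + h
            expected[h] = 0.5 * prev + 1.0 * x[t - 2] + 0.3 * x[t - 3]
            prev = expected[h]
        np.testing.assert_allclose(fc, expected, atol=1e-12)

    def test_one_step_on_training_equals_fitted(self):
        spec = SimSpec(T_train=400, T_test=0, input_ar=[0.5], noise_sd=0.3, seed=61)
        y, x, _ = generate_polytf(spec, delta=[1.2], omega=[0.4], d=2)
        model = fit_transfer_regression(y, [(x, 0, 2, 1)])
        off = model.offset
        p = predict_poly(model, y, [x], start=off + 1, horizon=len(y) - off)
        np.testing.assert_allclose(p, model.fitted, atol=1e-10)


class TestFivestepPipeline:
    def test_delay_identified_end_to_end(self):
        hits = 0
        for seed in range(20):
            sig = np.sqrt((4.0 / 3.0) / 4.0 * (1 - 0.09))
            spec = SimSpec(T_train=1000, T_test=0, input_ar=[0.5], noise_sd=sig,
                           seed=1700 + seed)
            y, x, _ = generate_polytf(spec, delta=[1.0], d=2, noise_ar=[0.3])
            model, report = fit_polytf(y, x, {"p": 1, "q": 0, "s": 0, "r": 0})
            hits += model.branches[0].d == 2
        assert hits >= 18

    def test_serialization_round_trip(self, tmp_path):
        spec = SimSpec(T_train=300, T_test=0, input_ar=[0.5], noise_sd=0.2, seed=71)
        y, x, _ = generate_polytf(spec, delta=[1.5], d=1)
        model, _ = fit_polytf(y, x, {"p": 1, "q": 0, "s": 0, "r": 0, "d": 1})
        path = tmp_path / "poly.json"
        model.to_json(path)
        loaded = PolyTFModel.from_json(path)
        fc1 = predict_poly(model, y[:250], [x], start=251, horizon=40)
        fc2 = predict_poly(loaded, y[:250], [x], start=251, horizon=40)
        np.testing.assert_array_equal(fc1, fc2)
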
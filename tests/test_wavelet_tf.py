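"""Two-stage least-squares estimation of time-varying transfer functions."""

import numpy as np
import pytest

from wavetf.wavelet_basis import WaveletBasisSpec, basis_matrix
from wavetf.wavelet_tf import (
    TVTFModel,
    fit_stage1,
    fit_stage2,
    predict,
    reconstruct_curve,
)
from wavetf.synthetic import CurveSpec, SimSpec, generate_tvtf

SCALING_ONLY = WaveletBasisSpec(4, 0, ())


def _ols(y, x, m, n):
    T = len(y)
    v = max(m, n)
    rows = np.arange(v, T)
    cols = [y[rows - i] for i in range(1, m + 1)] + [x[rows - j] for j in range(n + 1)]
    D = np.column_stack(cols)
    return np.linalg.lstsq(D, y[rows], rcond=None)[0]


class TestStage1:
    @pytest.mark.parametrize("m,n", [(m, n) for m in range(4) for n in range(4)
                                     if not (m == 0 and n == 0)])
    def test_scaling_only_equals_ols(self, rng, m, n):
        y = rng.normal(size=150)
        x = rng.normal(size=150)
        model = fit_stage1(y, x, m, n, SCALING_ONLY)
        ours = np.concatenate(
            [np.concatenate(model.delta_coefs) if m else np.array([])]
            + [np.concatenate(model.omega_coefs)]
        )
        np.testing.assert_allclose(ours, _ols(y, x, m, n), atol=1e-8)

    def test_noiseless_basis_representable_truth_recovered(self, rng):
        # build truth as exact combinations of the fitting basis
        T = 256
        basis = WaveletBasisSpec(4, 3, (0, 1, 2))
        grid = np.arange(1, T + 1) / T
        B = basis_matrix(basis, grid).matrix
        cd = np.zeros(basis.n_columns); cd[0] = 0.4; cd[1] = 0.1
        co = np.zeros(basis.n_columns); co[0] = 0.7; co[3] = -0.15
        d_true, o_true = B @ cd, B @ co
        x = rng.normal(size=T)
        y = np.zeros(T)
        for t in range(T):
            y[t] = o_true[t] * x[t] + (d_true[t] * y[t - 1] if t else 0.0)
        model = fit_stage1(y, x, 1, 0, basis)
        assert np.max(np.abs(model.delta_curves[0] - d_true[1:])) < 1e-6
        assert np.max(np.abs(model.omega_curves[0] - o_true[1:])) < 1e-6

    def test_residuals_orthogonal_to_design(self, tv_dataset):
        _, y, x, _ = tv_dataset
        basis = WaveletBasisSpec(4, 3, (0, 1, 2))
        model = fit_stage1(y, x, 1, 0, basis)
        from wavetf.wavelet_basis import build_design_matrices

        py, px, _, _ = build_design_matrices(y, x, basis, 1, 0)
        design = np.hstack([py, px])
        e = model.residuals
        num = np.abs(design.T @ e).max()
        assert num / (np.linalg.norm(design) * np.linalg.norm(e)) < 1e-8

    def test_curves_equal_basis_times_coefs(self, tv_dataset):
        _, y, x, _ = tv_dataset
        basis = WaveletBasisSpec(2, 3, (0, 2))
        model = fit_stage1(y, x, 1, 0, basis)
        B = basis_matrix(basis, model.u_grid).matrix
        np.testing.assert_allclose(model.delta_curves[0], B @ model.delta_coefs[0], atol=1e-10)

    def test_nesting_sse_monotone(self, tv_dataset):
        _, y, x, _ = tv_dataset
        sets = [(1,), (1, 2), (1, 2, 3), (1, 2, 3, 4)]
        sses = []
        for ls in sets:
            model = fit_stage1(y, x, 1, 0, WaveletBasisSpec(4, 5, ls))
            sses.append(np.sum(model.residuals**2))
        assert all(a >= b - 1e-9 for a, b in zip(sses, sses[1:]))


class TestStage2:
    def test_noiseless_stage2_residuals_zero(self, rng):
        T = 256
        basis = WaveletBasisSpec(1, 2)
        x = rng.normal(size=T)
        y = np.zeros(T)
        for t in range(T):
            y[t] = 0.8 * x[t] + (0.3 * y[t - 1] if t else 0.0)
        s1 = fit_stage1(y, x, 1, 0, basis)
        s2 = fit_stage2(s1, y, x)
        assert np.max(np.abs(s2.residuals)) < 1e-8

    def test_constant_coefficients_stage2_matches_stage1(self):
        # constant-coefficient data, scaling-only basis: the two stages must
        # agree within Monte-Carlo error (paired over seeds)
        diffs = []
        for seed in range(30):
            spec = SimSpec(
                T_train=400, T_test=0,
                delta=[CurveSpec("constant", a=0.5)],
                omega=[CurveSpec("constant", a=0.8)],
                noise_sd=0.2, seed=7000 + seed,
            )
            y, x, _ = generate_tvtf(spec)
            s1 = fit_stage1(y, x, 1, 0, SCALING_ONLY)
            s2 = fit_stage2(s1, y, x)
            diffs.append(s2.delta_coefs[0][0] - s1.delta_coefs[0][0])
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 2 * se + 5e-3

    def test_requires_fitted_stage1(self, tv_dataset):
        _, y, x, _ = tv_dataset
        s1 = fit_stage1(y, x, 1, 0, SCALING_ONLY)
        s2 = fit_stage2(s1, y, x)
        with pytest.raises(ValueError, match="stage-1"):
            fit_stage2(s2, y, x)

    def test_exact_innovation_decomposition(self, tv_dataset):
        # e2_t - delta_1(u_t) * e1_{t-1} reproduces the stored exact innovations
        _, y, x, _ = tv_dataset
        basis = WaveletBasisSpec(4, 3, (0, 1, 2))
        s1 = fit_stage1(y, x, 1, 0, basis)
        s2 = fit_stage2(s1, y, x)
        d1 = s2.delta_curves[0]
        expected = s2.residuals[1:] - d1[1:] * s1.residuals[:-1]
        np.testing.assert_allclose(s2.innovations_exact[1:], expected, atol=1e-12)


class TestReconstruction:
    def test_constant_curve(self):
        basis = WaveletBasisSpec(4, 2)
        coefs = np.zeros(basis.n_columns)
        coefs[0] = 3.25
        np.testing.assert_allclose(
            reconstruct_curve(coefs, basis, np.linspace(0.01, 0.99, 11)), 3.25
        )

    def test_haar_step(self):
        basis = WaveletBasisSpec(1, 1)
        coefs = np.array([0.0, 1.0])  # alpha=0, beta_{0,0}=1
        vals = reconstruct_curve(coefs, basis, [0.2, 0.7])
        np.testing.assert_array_equal(vals, [1.0, -1.0])

    def test_projection_error_shrinks_with_level(self):
        # quadrature projection of sin(2 pi u) onto D4 bases of growing J
        grid = (np.arange(2**13) + 0.5) / 2**13
        f = np.sin(2 * np.pi * grid)
        errs = []
        for J in (2, 3, 4):
            basis = WaveletBasisSpec(4, J)
            B = basis_matrix(basis, grid).matrix
            coefs = (B.T @ f) / len(grid)  # quadrature inner products
            errs.append(np.max(np.abs(B @ coefs - f)))
        assert errs[0] > errs[1] > errs[2]

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            reconstruct_curve([1.0, 2.0], WaveletBasisSpec(2, 2), [0.5])


class TestPredict:
    def test_one_step_on_training_equals_fitted(self, tv_dataset):
        _, y, x, _ = tv_dataset
        basis = WaveletBasisSpec(4, 3, (0, 1, 2))
        model = fit_stage1(y[:512], x[:512], 1, 0, basis)
        p = predict(model, y[:512], x[:512], start=2, horizon=511, mode="one_step")
        np.testing.assert_allclose(p, model.fitted, atol=1e-10)

    def test_constant_model_matches_arx_recursion(self, rng):
        spec = SimSpec(
            T_train=300, T_test=30,
            delta=[CurveSpec("constant", a=0.5)],
            omega=[CurveSpec("constant", a=0.8)],
            noise_sd=0.2, seed=11,
        )
        y, x, _ = generate_tvtf(spec)
        model = fit_stage1(y[:300], x[:300], 1, 0, SCALING_ONLY)
        d1 = model.delta_coefs[0][0]
        w0 = model.omega_coefs[0][0]
        fc = predict(model, y, x, mode="recursive")
        expected = np.empty(30)
        prev = y[299]
        for h in range(30):
            expected[h] = d1 * prev + w0 * x[300 + h]
            prev = expected[h]
        np.testing.assert_allclose(fc, expected, atol=1e-10)

    def test_zero_noise_one_step_forecast_exact(self, rng):
        # constant curves + no noise: frozen-boundary forecasts are exact
        spec = SimSpec(
            T_train=256, T_test=32,
            delta=[CurveSpec("constant", a=0.4)],
            omega=[CurveSpec("constant", a=0.9)],
            noise_sd=0.0, seed=3,
        )
        y, x, _ = generate_tvtf(spec)
        model = fit_stage1(y[:256], x[:256], 1, 0, SCALING_ONLY)
        fc = predict(model, y, x, mode="one_step")
        assert np.max(np.abs(fc - y[256:])) < 1e-8

    def test_missing_future_inputs_error(self, tv_dataset):
        _, y, x, _ = tv_dataset
        model = fit_stage1(y[:512], x[:512], 1, 0, SCALING_ONLY)
        with pytest.raises(ValueError, match="too short"):
            predict(model, y[:512], x[:512], start=513, horizon=10)


class TestSerialization:
    def test_json_round_trip_forecasts_identical(self, tmp_path, tv_dataset):
        _, y, x, _ = tv_dataset
        basis = WaveletBasisSpec(4, 3, (0, 1, 2))
        s1 = fit_stage1(y[:512], x[:512], 1, 0, basis)
        model = fit_stage2(s1, y[:512], x[:512])
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = TVTFModel.from_json(path)
        fc1 = predict(model, y, x, mode="one_step")
        fc2 = predict(loaded, y, x, mode="one_step")
        np.testing.assert_array_equal(fc1, fc2)


class TestParameterRecovery:
    def test_integrated_squared_error_shrinks_with_T(self):
        # delta_1(u) = 0.4 + 0.2 cos(2 pi u), omega_0(u) = 0.8 - 0.4 u
        def median_ise(T, reps=15):
            errs = []
            for s in range(reps):
                spec = SimSpec(
                    T_train=T, T_test=0,
                    delta=[CurveSpec("cosine", a=0.4, b=0.2)],
                    omega=[CurveSpec("linear", a=0.8, b=-0.4)],
                    noise_sd=0.1, seed=5000 + s,
                )
                y, x, curves = generate_tvtf(spec)
                model = fit_stage1(y, x, 1, 0, WaveletBasisSpec(4, 3, (0, 1, 2)))
                err = model.delta_curves[0] - curves["delta_1"][model.v:]
                errs.append(np.mean(err**2))
            return np.median(errs)

        medians = [median_ise(T) for T in (256, 512, 1024)]
        assert medians[0] > medians[1] > medians[2]
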
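"""Wiener decoder: design matrix layout, OLS exactness, transfer paths."""

import numpy as np
import pytest
from scipy.stats import ortho_group

from latentemg.align import fit_cca, identity_aligner
from latentemg.decode import (build_lagged_design, fit_wiener, predict,
                              train_direct, transfer_decode, trial_bounds_for)


def _toy_latents(rng, n_trials=4, nb=75, p=13):
    # jitter keeps the lagged design full rank (pure sinusoids would make
    # lagged copies linearly dependent)
    t = np.linspace(0, 2 * np.pi, nb)
    trials = [np.stack([np.sin((k + 1) * t + rng.uniform(0, np.pi))
                        for k in range(p)], axis=1)
              + 0.01 * rng.normal(size=(nb, p)) for _ in range(n_trials)]
    return np.vstack(trials), trial_bounds_for(n_trials, nb)


class TestLaggedDesign:
    def test_constant_latents_constant_columns(self):
        lat = np.full((30, 3), 2.5)
        x = build_lagged_design(lat, [(0, 30)], n_lags=4)
        assert (x.std(axis=0) == 0).all()
        assert (x[:, 0] == 1).all()

    def test_single_lag_is_intercept_plus_latents(self, rng):
        lat = rng.normal(size=(20, 5))
        x = build_lagged_design(lat, [(0, 20)], n_lags=1)
        assert np.array_equal(x[:, 1:], lat)

    def test_index_arithmetic_oracle(self, rng):
        lat, bounds = _toy_latents(rng, n_trials=1, nb=75, p=13)
        x = build_lagged_design(lat, bounds, n_lags=5)
        assert x.shape == (75, 66)
        row10 = np.concatenate([[1.0]] + [lat[10 - lag] for lag in range(5)])
        assert np.array_equal(x[10], row10)

    def test_history_never_crosses_trials(self, rng):
        lat, bounds = _toy_latents(rng, n_trials=2, nb=10, p=2)
        x = build_lagged_design(lat, bounds, n_lags=3)
        # first row of the second trial sees only its own first sample
        assert np.array_equal(x[10, 1:], np.tile(lat[10], 3))

    def test_invalid_lags_rejected(self, rng):
        with pytest.raises(ValueError):
            build_lagged_design(rng.normal(size=(10, 2)), [(0, 10)], n_lags=0)


class TestFitWiener:
    def test_normal_equations_oracle(self, rng):
        x = np.column_stack([np.ones(20), rng.normal(size=(20, 4))])
        y = rng.normal(size=(20, 2))
        d = fit_wiener(x, y, n_lags=1)
        oracle = np.linalg.solve(x.T @ x, x.T @ y)
        assert np.abs(d.weights - oracle).max() < 1e-8

    def test_residuals_orthogonal_to_design(self, rng):
        x = np.column_stack([np.ones(50), rng.normal(size=(50, 6))])
        y = rng.normal(size=(50, 3))
        d = fit_wiener(x, y, n_lags=1)
        r = y - x @ d.weights
        for j in range(x.shape[1]):
            num = abs(x[:, j] @ r).max()
            assert num < 1e-6 * np.linalg.norm(x[:, j]) * np.linalg.norm(r, axis=0).max()

    def test_exact_linear_target_interpolated(self, rng):
        lat, bounds = _toy_latents(rng, n_trials=2, p=4)
        x = build_lagged_design(lat, bounds, n_lags=3)
        w = rng.normal(size=(x.shape[1], 2))
        y = x @ w
        y += 1.0 - y.min(axis=0)  # positive targets keep rectification inactive
        d = fit_wiener(x, y, n_lags=3)
        pred = predict(d, lat, bounds)
        assert 1 - ((y - pred) ** 2).sum() / ((y - y.mean(0)) ** 2).sum() > 1 - 1e-8

    def test_rank_deficient_design_rejected(self, rng):
        x = np.column_stack([np.ones(30), rng.normal(size=(30, 3))])
        x = np.column_stack([x, x[:, 1]])  # duplicated column
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            fit_wiener(x, rng.normal(size=30), n_lags=1)


class TestPredict:
    def test_zero_latents_yield_rectified_intercept(self, rng):
        lat, bounds = _toy_latents(rng, n_trials=1, p=3)
        x = build_lagged_design(lat, bounds, n_lags=2)
        d = fit_wiener(x, rng.normal(size=(75, 2)), n_lags=2)
        pred = predict(d, np.zeros_like(lat[:, :3]), bounds)
        assert np.allclose(pred, np.maximum(d.weights[0], 0.0))

    def test_outputs_nonnegative(self, rng):
        lat, bounds = _toy_latents(rng)
        d = fit_wiener(build_lagged_design(lat, bounds, 5),
                       rng.normal(size=(lat.shape[0], 3)), 5)
        assert (predict(d, rng.normal(size=lat.shape), bounds) >= 0).all()

    def test_heldout_r2_on_noiseless_linear_readout(self, rng):
        lat, bounds = _toy_latents(rng, n_trials=8, p=5)
        w = rng.normal(size=(5, 3))
        y = lat @ w + 4.0
        tr = slice(0, 6 * 75)
        te = slice(6 * 75, 8 * 75)
        d = train_direct(lat[tr], y[tr], trial_bounds_for(6, 75), n_lags=5)
        pred = predict(d, lat[te], trial_bounds_for(2, 75))
        sse = ((y[te] - pred) ** 2).sum()
        sst = ((y[te] - y[te].mean(0)) ** 2).sum()
        assert 1 - sse / sst > 0.99

    def test_rectification_never_hurts_nonnegative_targets(self, rng):
        lat, bounds = _toy_latents(rng, n_trials=4, p=4)
        y = np.maximum(lat @ rng.normal(size=(4, 2)), 0.0)
        x = build_lagged_design(lat, bounds, 5)
        d = fit_wiener(x, y, 5)
        raw = x @ d.weights
        rect = np.maximum(raw, 0.0)
        sse_raw = ((y - raw) ** 2).sum()
        sse_rect = ((y - rect) ** 2).sum()
        assert sse_rect <= sse_raw + 1e-12


class TestTransfer:
    def test_identity_fit_matches_within_predictions(self, rng):
        lat, bounds = _toy_latents(rng, n_trials=4, p=5)
        y = np.maximum(lat @ rng.normal(size=(5, 2)) + 1.0, 0.0)
        d = train_direct(lat, y, bounds)
        al = fit_cca(lat, lat)
        pred_transfer = transfer_decode(d, al, lat, bounds)
        pred_within = predict(d, lat, bounds)
        assert np.abs(pred_transfer - pred_within).max() < 1e-8

    def test_orthogonal_mixing_recovered(self, rng):
        lat, bounds = _toy_latents(rng, n_trials=6, p=5)
        y = lat @ rng.normal(size=(5, 2)) + 4.0
        d = train_direct(lat, y, bounds)
        r = ortho_group.rvs(5, random_state=0)
        al = fit_cca(lat, lat @ r)
        pred = transfer_decode(d, al, lat @ r, bounds)
        sse = ((y - pred) ** 2).sum()
        sst = ((y - y.mean(0)) ** 2).sum()
        assert 1 - sse / sst > 0.99

    def test_identity_aligner_fails_on_mixed_latents(self, rng):
        lat, bounds = _toy_latents(rng, n_trials=6, p=5)
        y = lat @ rng.normal(size=(5, 2)) + 4.0
        d = train_direct(lat, y, bounds)
        mixed = lat @ (rng.normal(size=(5, 5)) + 2 * np.eye(5))
        good = transfer_decode(d, fit_cca(lat, mixed), mixed, bounds)
        bad = transfer_decode(d, identity_aligner(5), mixed, bounds)
        assert ((y - bad) ** 2).sum() > ((y - good) ** 2).sum()
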
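"""Metrics, fold bookkeeping, and experiment-harness behavior."""

import numpy as np
import pandas as pd
import pytest

from latentemg.evaluate import (decode_pair, dayk_experiment,
                                generalization_experiment, make_folds,
                                offset_search, run_pair_experiment,
                                weighted_r2)
from latentemg.synth import WorldConfig, generate_session, generate_world


class TestWeightedR2:
    def test_perfect_prediction(self, rng):
        y = rng.normal(size=(50, 3)) ** 2
        assert weighted_r2(y, y).weighted_r2 == pytest.approx(1.0)

    def test_mean_prediction_is_zero(self, rng):
        y = rng.normal(size=(50, 3))
        pred = np.tile(y.mean(0), (50, 1))
        assert weighted_r2(pred, y).weighted_r2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_toy(self):
        y = np.array([[0., 0.], [1., 2.], [2., 4.], [3., 6.]])
        yh = np.array([[0., 1.], [1., 1.], [2., 5.], [3., 5.]])
        res = weighted_r2(yh, y)
        assert res.per_muscle_r2["m0"] == pytest.approx(1.0)
        assert res.per_muscle_r2["m1"] == pytest.approx(0.8)
        assert res.weighted_r2 == pytest.approx(0.84)

    def test_equal_variances_reduce_to_unweighted_mean(self, rng):
        y = rng.normal(size=(100, 2))
        y[:, 1] = y[:, 0] * -1  # equal variance, different signal
        pred = rng.normal(size=(100, 2))
        res = weighted_r2(pred, y)
        assert res.weighted_r2 == pytest.approx(
            np.mean(list(res.per_muscle_r2.values())))

    def test_zero_variance_muscle_excluded(self, rng):
        y = rng.normal(size=(50, 2))
        y[:, 1] = 3.0
        with pytest.warns(UserWarning, match="zero-variance"):
            res = weighted_r2(y, y)
        assert list(res.per_muscle_r2) == ["m0"]


def _table(counts_per_target, n_targets=8):
    labels = np.repeat(np.arange(n_targets) * 45.0, counts_per_target)
    return pd.DataFrame({"trial_id": np.arange(len(labels)),
                         "target_deg": labels,
                         "go_cue_s": np.arange(len(labels), dtype=float),
                         "onset_s": np.arange(len(labels)) + 0.25})


class TestFolds:
    def test_paper_fold_sizes(self):
        folds = make_folds(_table(16), k=4)
        for f in range(4):
            assert (folds == f).sum() == 32
            assert (folds != f).sum() == 96

    def test_sparse_session_three_folds(self):
        folds = make_folds(_table(3), k=3)
        for f in range(3):
            sub = _table(3)[folds == f]
            assert len(sub) == 8
            assert sub.target_deg.nunique() == 8

    def test_partition_property(self):
        folds = make_folds(_table(5), k=4, seed=3)
        assert (folds >= 0).all() and (folds < 4).all()

    def test_oversized_k_rejected(self):
        with pytest.raises(ValueError):
            make_folds(_table(3), k=4)

    def test_deterministic_in_seed(self):
        assert np.array_equal(make_folds(_table(6), 3, seed=9),
                              make_folds(_table(6), 3, seed=9))


class TestHarness:
    def test_direct_on_self_equals_within(self, twin_prepared):
        a, _ = twin_prepared
        rw = decode_pair(a, None, "within", 4, seed=5)
        rd = decode_pair(a, a, "direct", 4, seed=5)
        assert rd.fold_r2 == rw.fold_r2

    def test_shuffled_correspondence_degrades_direct(self, twin_prepared):
        # wrong-target pairing: permute the target session's labels
        a, b = twin_prepared
        matched = decode_pair(a, b, "direct", 4, seed=5).r2
        shuffled = []
        for perm_seed in range(3):
            rng = np.random.default_rng(perm_seed)
            tbl = b.table.copy()
            tbl["target_deg"] = rng.permutation(tbl["target_deg"].to_numpy())
            broken = type(b)(b.session, b.rates, b.env, b.muscle_names, tbl,
                             b.bin_width)
            shuffled.append(decode_pair(a, broken, "direct", 4, seed=5).r2)
        assert np.median(shuffled) < matched

    def test_pair_matrix_layout(self, twin_prepared):
        a, b = twin_prepared
        pm = run_pair_experiment([a, b], "transfer", k=4, seed=5)
        assert pm.values.shape == (2, 2)
        assert not np.isnan(pm.values).any()
        # diagonal entries are within-session accuracy, typically the ceiling
        assert pm.values[0, 0] > 0.5 and pm.values[1, 1] > 0.5

    def test_offset_curve_length_matches_grid(self, twin_prepared):
        a, b = twin_prepared
        grid = np.array([-0.6, -0.5, -0.4])
        curve, best = offset_search(b, a, grid, "direct", k=4, seed=5,
                                    length=1.2)
        assert curve.shape == grid.shape
        assert best in grid

    def test_empty_offset_grid_rejected(self, twin_prepared):
        a, b = twin_prepared
        with pytest.raises(ValueError):
            offset_search(b, a, [], "direct")

    def test_generalization_empty_sets_rejected(self, twin_prepared):
        a, b = twin_prepared
        with pytest.raises(ValueError):
            generalization_experiment(a, b, [], [0.0])

    def test_generalization_full_matches_train_eval_ceiling(self, twin_prepared):
        a, b = twin_prepared
        alldirs = list(np.arange(8) * 45.0)
        res = generalization_experiment(a, b, alldirs, alldirs, "direct", seed=5)
        # training directions = test directions: fit-on-all evaluation ceiling
        assert res.weighted_r2 > decode_pair(a, b, "direct", 4, seed=5).r2 - 0.05

    def test_zero_drift_dayk_alignment_is_neutral(self):
        w = generate_world(WorldConfig(seed=21, n_subjects=2))
        src = generate_session(w, 0, 0, 10)
        days = [generate_session(w, 1, k, 10) for k in range(2)]
        df = dayk_experiment(src, days, seed=5)
        assert np.abs(df.r2_fixed - df.r2_aligned).max() < 0.02

    def test_label_permutation_never_beats_matched_cv(self, twin_prepared):
        # leakage guard: destroying the trial correspondence must not help
        a, b = twin_prepared
        matched = decode_pair(a, b, "transfer", 4, seed=5).r2
        perms = []
        for perm_seed in range(5):
            rng = np.random.default_rng(100 + perm_seed)
            tbl = b.table.copy()
            tbl["target_deg"] = rng.permutation(tbl["target_deg"].to_numpy())
            broken = type(b)(b.session, b.rates, b.env, b.muscle_names, tbl,
                             b.bin_width)
            perms.append(decode_pair(a, broken, "transfer", 4, seed=5).r2)
        assert np.median(perms) < matched
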
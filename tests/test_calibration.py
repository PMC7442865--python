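"""Network training, trial selection, splitting, and parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from acutono import calibration
from acutono.calibration import (
    CalibrationModel,
    split_data,
    train_once,
    trial_score,
    run_trials,
    scan_architectures,
    predict_iop,
)


def linear_dataset(n=100, noise=0.0, seed=0, slope=1.0):
    """y = slope*x1 (+ noise) with 9 covariates; unique subject per row."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 9))
    cols = {f"x{i}": x[:, i] for i in range(9)}
    df = pd.DataFrame(cols)
    df["subject_id"] = [f"P{i}" for i in range(n)]
    df["reference_iop"] = slope * x[:, 0] + noise * rng.standard_normal(n)
    return df, [f"x{i}" for i in range(9)]


class TestSplitData:
    def test_exact_sizes_with_singleton_subjects(self):
        df, _ = linear_dataset(100)
        tr, va, te = split_data(df, (0.7, 0.15, 0.15), seed=1)
        assert (len(tr), len(va), len(te)) == (70, 15, 15)

    def test_disjoint_and_exhaustive(self):
        df, _ = linear_dataset(100)
        tr, va, te = split_data(df, seed=2)
        idx = sorted([*tr.index, *va.index, *te.index])
        assert idx == list(range(100))

    def test_same_seed_reproduces_split(self):
        df, _ = linear_dataset(80)
        a = split_data(df, seed=5)
        b = split_data(df, seed=5)
        for pa, pb in zip(a, b):
            assert list(pa.index) == list(pb.index)

    def test_stratification_on_constructed_set(self):
        # 30 points, 10 per IOP tertile; equal thirds -> every split must
        # hold each tertile's proportion to within one sample
        df, _ = linear_dataset(30, seed=3)
        df["reference_iop"] = np.r_[np.full(10, 10.0), np.full(10, 16.0), np.full(10, 25.0)]
        parts = split_data(df, (1 / 3, 1 / 3, 1 / 3), seed=0)
        for part in parts:
            for level in (10.0, 16.0, 25.0):
                n_level = int((part["reference_iop"] == level).sum())
                assert abs(n_level - len(part) / 3) <= 1

    def test_groups_stay_together(self):
        df, _ = linear_dataset(120)
        df["subject_id"] = [f"P{i // 2}" for i in range(120)]  # 2 rows per subject
        tr, va, te = split_data(df, seed=4)
        seen = {}
        for name, part in (("tr", tr), ("va", va), ("te", te)):
            for s in part["subject_id"]:
                assert seen.setdefault(s, name) == name

    def test_bad_fractions_and_small_data_raise(self):
        df, _ = linear_dataset(100)
        with pytest.raises(ValueError):
            split_data(df, (0.5, 0.5, 0.2))
        with pytest.raises(ValueError):
            split_data(linear_dataset(20)[0])


class TestTrainOnce:
    def test_learns_linear_target(self):
        df, cols = linear_dataset(200, seed=1)
        tr, va, te = split_data(df, seed=1)
        m = train_once(tr, va, architecture=(7, 10), seed=0, feature_columns=cols)
        rmse = np.sqrt(np.mean((m.predict(va) - va["reference_iop"]) ** 2))
        assert rmse < 0.05

    def test_same_seed_gives_identical_weights(self):
        df, cols = linear_dataset(100, seed=2)
        tr, va, _ = split_data(df, seed=2)
        m1 = train_once(tr, va, seed=9, feature_columns=cols)
        m2 = train_once(tr, va, seed=9, feature_columns=cols)
        for w1, w2 in zip(m1.weights, m2.weights):
            assert np.array_equal(w1, w2)

    def test_noiseless_cohort_recovers_iop_below_one_mmhg(
        self, small_noiseless_features, small_noiseless_ensemble
    ):
        # the forward model is invertible, so a trained net must recover the
        # latent IOP from noiseless features almost exactly
        ens = small_noiseless_ensemble
        test = small_noiseless_features.loc[ens.test_index]
        rmse = np.sqrt(np.mean((ens.predict(test) - test["reference_iop"]) ** 2))
        assert rmse < 1.0

    def test_model_json_roundtrip(self, tmp_path):
        df, cols = linear_dataset(100, seed=5)
        tr, va, _ = split_data(df, seed=5)
        m = train_once(tr, va, seed=1, feature_columns=cols)
        m.to_json(tmp_path / "m.json")
        back = CalibrationModel.from_json(tmp_path / "m.json")
        assert np.allclose(back.predict(va), m.predict(va))


class TestTrialScore:
    def _model_with_predictions(self, va, preds, cols):
        class Fake:
            feature_names = cols

            def predict(self, features):
                return np.asarray(preds)[: len(features)]

        return Fake()

    def test_perfect_predictions_score_best(self):
        df, cols = linear_dataset(40, seed=0)
        fake = self._model_with_predictions(df, df["reference_iop"].to_numpy(), cols)
        t = trial_score(fake, df)
        assert t.slope == pytest.approx(1.0)
        assert t.r == pytest.approx(1.0)
        assert t.slope_dev == pytest.approx(0.0, abs=1e-12)
        assert t.r_deficit == pytest.approx(0.0, abs=1e-12)

    def test_constant_predictions_score_worst(self):
        df, cols = linear_dataset(40, seed=0)
        fake = self._model_with_predictions(df, np.full(40, 3.0), cols)
        t = trial_score(fake, df)
        assert t.slope_dev == np.inf and t.r_deficit == np.inf

    def test_slope_closer_to_one_ranks_better_at_equal_r(self):
        df, cols = linear_dataset(40, seed=0)
        y = df["reference_iop"].to_numpy()
        t_good = trial_score(self._model_with_predictions(df, 0.9 * y, cols), df)
        t_bad = trial_score(self._model_with_predictions(df, 0.7 * y, cols), df)
        assert t_good.r == pytest.approx(t_bad.r)
        assert t_good.slope_dev < t_bad.slope_dev


class TestRunTrials:
    def test_keep_fraction_selects_expected_count(self):
        df, cols = linear_dataset(80, seed=3)
        ens = run_trials(df, n_trials=10, keep_fraction=0.2, seed=0,
                         feature_columns=cols, max_iter=50)
        assert len(ens.selected) == 2

    def test_selected_subset_scores_no_worse_than_average(self):
        df, cols = linear_dataset(80, noise=0.5, seed=4)
        ens = run_trials(df, n_trials=12, keep_fraction=0.25, seed=1,
                         feature_columns=cols, max_iter=60)
        scores = np.array([t.slope_dev + t.r_deficit for t in ens.metrics])
        assert scores[ens.selected].mean() <= scores.mean() + 1e-12

    def test_seed_reproducibility_of_whole_ensemble(self):
        df, cols = linear_dataset(80, seed=5)
        a = run_trials(df, n_trials=10, keep_fraction=0.2, seed=2,
                       feature_columns=cols, max_iter=40)
        b = run_trials(df, n_trials=10, keep_fraction=0.2, seed=2,
                       feature_columns=cols, max_iter=40)
        assert np.array_equal(a.selected, b.selected)
        for ma, mb in zip(a.models, b.models):
            for wa, wb in zip(ma.weights, mb.weights):
                assert np.array_equal(wa, wb)

    def test_test_split_isolation(self, small_noiseless_ensemble):
        small_noiseless_ensemble.assert_test_isolation()

    def test_noiseless_recovery_slope(self, small_noiseless_features,
                                      small_noiseless_ensemble):
        ens = small_noiseless_ensemble
        test = small_noiseless_features.loc[ens.test_index]
        slope, _, r = __import__("acutono").agreement.regression_analysis(
            test["reference_iop"].to_numpy(), ens.predict(test)
        )
        assert slope >= 0.9
        assert r >= 0.99


class TestPredictIop:
    def test_keyed_inputs_are_order_invariant(self):
        df, cols = linear_dataset(100, seed=6)
        tr, va, _ = split_data(df, seed=6)
        m = train_once(tr, va, seed=0, feature_columns=cols)
        row = va.iloc[[0]]
        shuffled = row[list(reversed(row.columns))]
        assert predict_iop(m, shuffled)[0] == pytest.approx(predict_iop(m, row)[0])

    def test_ensemble_prediction_is_mean_of_members(self, small_noiseless_features,
                                                    small_noiseless_ensemble):
        ens = small_noiseless_ensemble
        test = small_noiseless_features.loc[ens.test_index].head(5)
        member_preds = np.stack([m.predict(test) for m in ens.selected_models])
        assert np.allclose(ens.predict(test), member_preds.mean(axis=0))

    def test_extrapolation_warns(self):
        df, cols = linear_dataset(100, seed=7)
        tr, va, _ = split_data(df, seed=7)
        m = train_once(tr, va, seed=0, feature_columns=cols)
        far = va.iloc[[0]].copy()
        far[cols[0]] = 100.0
        with pytest.warns(UserWarning, match="extrapolation"):
            predict_iop(m, far)


class TestScanArchitectures:
    def test_small_grid_structure_and_score_spread(self):
        df, cols = linear_dataset(80, seed=8)
        table = scan_architectures(df, neuron_range=range(5, 7),
                                   n_trials_per_arch=10, seed=0,
                                   feature_columns=cols, max_iter=40)
        assert len(table) == 4
        assert set(zip(table["h1"], table["h2"])) == {(5, 5), (5, 6), (6, 5), (6, 6)}
        # every architecture can represent a linear map, so scores stay close
        assert table["mean_score"].max() < 2 * max(table["mean_score"].min(), 0.01)
        assert list(table["rank"]) == sorted(table["rank"])


def test_sklearn_mlp_agrees_iop_is_recoverable(small_noiseless_features):
    """Independent cross-check: an off-the-shelf MLP also inverts the
    noiseless feature->IOP map to within ~1 mm Hg."""
    from sklearn.neural_network import MLPRegressor

    from acutono.pipeline import FEATURE_COLUMNS

    df = small_noiseless_features
    tr, va, te = split_data(df, seed=0)
    x = tr[FEATURE_COLUMNS].to_numpy()
    mu, sd = x.mean(0), x.std(0)
    reg = MLPRegressor(hidden_layer_sizes=(7, 10), activation="tanh", solver="lbfgs",
                       max_iter=2000, random_state=0)
    reg.fit((x - mu) / sd, tr["reference_iop"])
    pred = reg.predict((te[FEATURE_COLUMNS].to_numpy() - mu) / sd)
    rmse = np.sqrt(np.mean((pred - te["reference_iop"]) ** 2))
    assert rmse < 1.5
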
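import numpy as np
import pandas as pd
import pytest

from brainpad_lab import brainage as ba
from brainpad_lab.morphometry import VoxelGrid


def feature_matrix(X, prefix="f"):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return ba.FeatureMatrix(
        X=X,
        columns=[f"{prefix}{i}" for i in range(X.shape[1])],
        subject_ids=[f"S{i:04d}" for i in range(X.shape[0])],
        n_voxels=0,
        vendor_levels=["only"],
    )


def tiny_maps_and_pheno(n_subjects=3, n_mask=10, vendors=("A",)):
    rng = np.random.default_rng(0)
    shape = (3, 3, 3)
    mask = np.zeros(shape, dtype=bool)
    mask.ravel()[:n_mask] = True
    maps, rows = {}, []
    for i in range(n_subjects):
        sid = f"S{i:04d}"
        maps[sid] = {
            t: VoxelGrid(rng.random(shape), (8.0,) * 3, mask, tissue=t)
            for t in ("GM", "WM", "CSF")
        }
        rows.append(
            {
                "subject_id": sid,
                "group": "HC_train",
                "sex": "F" if i % 2 else "M",
                "age": 40.0 + i,
                "vendor": vendors[i % len(vendors)],
                "field_strength": 3.0,
            }
        )
    return maps, pd.DataFrame(rows)


class TestAssembleFeatures:
    def test_column_count_single_vendor(self):
        maps, pheno = tiny_maps_and_pheno(n_subjects=3, n_mask=10)
        fm = ba.assemble_features(maps, pheno)
        assert fm.X.shape == (3, 3 * 10 + 7)

    def test_column_count_two_vendors_drop_first(self):
        maps, pheno = tiny_maps_and_pheno(n_subjects=4, n_mask=10, vendors=("A", "B"))
        fm = ba.assemble_features(maps, pheno)
        assert fm.X.shape == (4, 3 * 10 + 6 + 1)

    def test_fullscale_mask_column_count(self):
        from brainpad_lab.synthcohort import fullscale_mask

        mask = fullscale_mask()
        maps, pheno = tiny_maps_and_pheno(n_subjects=2)
        for sid in maps:
            for t in maps[sid]:
                g = maps[sid][t]
                maps[sid][t] = VoxelGrid(
                    np.zeros(mask.shape), (8.0,) * 3, mask, tissue=t
                )
        fm = ba.assemble_features(maps, pheno)
        assert fm.X.shape[1] == 3 * 3747 + 7 == 11248

    def test_zero_subjects_rejected(self):
        maps, pheno = tiny_maps_and_pheno()
        with pytest.raises(ValueError, match="zero"):
            ba.assemble_features(maps, pheno.iloc[:0])

    def test_missing_tissue_map_names_subject(self):
        maps, pheno = tiny_maps_and_pheno()
        del maps["S0001"]["WM"]
        with pytest.raises(KeyError, match="S0001"):
            ba.assemble_features(maps, pheno)

    def test_inconsistent_mask_rejected(self):
        maps, pheno = tiny_maps_and_pheno()
        g = maps["S0002"]["GM"]
        other = np.zeros_like(g.mask)
        other.ravel()[5:15] = True
        maps["S0002"]["GM"] = VoxelGrid(g.values, g.spacing, other, tissue="GM")
        with pytest.raises(ValueError, match="mask"):
            ba.assemble_features(maps, pheno)


class TestSplit:
    def make_hc(self, n):
        return pd.DataFrame(
            {"subject_id": [f"S{i}" for i in range(n)], "group": "HC_train"}
        )

    def test_1054_at_090_gives_949_105(self):
        train, hold = ba.split_train_holdout(self.make_hc(1054), 0.9, seed=0)
        assert (len(train), len(hold)) == (949, 105)
        assert set(train) | set(hold) == set(f"S{i}" for i in range(1054))
        assert not set(train) & set(hold)

    def test_rounding_on_10(self):
        train, hold = ba.split_train_holdout(self.make_hc(10), 0.9, seed=0)
        assert (len(train), len(hold)) == (9, 1)

    def test_same_seed_same_partition(self):
        a = ba.split_train_holdout(self.make_hc(50), 0.8, seed=4)
        b = ba.split_train_holdout(self.make_hc(50), 0.8, seed=4)
        assert a == b

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            ba.split_train_holdout(self.make_hc(10), 1.5)


class TestTrain:
    def test_identity_feature_recovers_age(self):
        rng = np.random.default_rng(1)
        ages = rng.uniform(20, 90, 60)
        fm = feature_matrix(ages)
        model = ba.train_age_model(fm, ages, C=100.0, epsilon=0.01)
        pred = model.predict(fm)
        assert np.max(np.abs(pred - ages)) < 0.5

    def test_pure_noise_features_give_constant_like_mae(self):
        rng = np.random.default_rng(2)
        ages = rng.uniform(20, 90, 300)
        fm_train = feature_matrix(rng.standard_normal((300, 3)))
        model = ba.train_age_model(fm_train, ages)
        ages_test = rng.uniform(20, 90, 300)
        fm_test = feature_matrix(rng.standard_normal((300, 3)))
        pred = model.predict(fm_test)
        mae = np.mean(np.abs(pred - ages_test))
        # best constant predictor under L1: median of the training ages
        oracle = np.mean(np.abs(ages_test - np.median(ages)))
        assert abs(mae - oracle) / oracle < 0.15

    def test_duplicated_columns_prediction_invariance(self):
        # duplicating every feature doubles the linear kernel, so the same
        # predictions are recovered exactly at half the regularization cost
        rng = np.random.default_rng(3)
        ages = rng.uniform(30, 80, 40)
        X = rng.standard_normal((40, 4))
        m1 = ba.train_age_model(feature_matrix(X), ages, C=1.0)
        m2 = ba.train_age_model(feature_matrix(np.hstack([X, X])), ages, C=0.5)
        p1 = m1.predict(feature_matrix(X))
        p2 = m2.predict(feature_matrix(np.hstack([X, X])))
        assert np.allclose(p1, p2, atol=1e-6)

    def test_constant_age_rejected(self):
        fm = feature_matrix(np.random.default_rng(0).standard_normal((12, 2)))
        with pytest.raises(ValueError, match="degenerate"):
            ba.train_age_model(fm, np.full(12, 50.0))

    def test_model_roundtrip_serialization(self, tmp_path):
        rng = np.random.default_rng(4)
        ages = rng.uniform(20, 90, 30)
        fm = feature_matrix(rng.standard_normal((30, 5)))
        model = ba.train_age_model(fm, ages)
        model.bias_alpha, model.bias_beta = 0.1, -2.0
        model.save(tmp_path / "model")
        loaded = ba.AgeModel.load(tmp_path / "model")
        assert np.allclose(loaded.predict(fm), model.predict(fm))
        assert loaded.bias_alpha == 0.1


class TestCrossval:
    def test_leave_one_out_boundary(self):
        rng = np.random.default_rng(5)
        ages = rng.uniform(30, 70, 12)
        fm = feature_matrix(ages + rng.normal(0, 1, 12))
        m = ba.crossval_metrics(fm, ages, k=12, seed=0)
        assert np.isfinite([m.mae, m.rmse, m.r2]).all()

    def test_every_subject_predicted_once(self):
        rng = np.random.default_rng(6)
        ages = rng.uniform(30, 70, 25)
        fm = feature_matrix(rng.standard_normal((25, 2)))
        preds = ba.crossval_predictions(fm, ages, k=5, seed=1)
        assert preds.shape == (25,)
        assert np.isfinite(preds).all()

    def test_noiseless_linear_pooled_mae_below_one_year(self):
        rng = np.random.default_rng(7)
        ages = rng.uniform(20, 90, 200)
        X = np.column_stack([ages, rng.standard_normal(200)])
        m = ba.crossval_metrics(feature_matrix(X), ages, k=10, seed=2, C=100.0)
        assert m.mae < 1.0

    def test_k_exceeding_n_rejected(self):
        fm = feature_matrix(np.arange(5.0))
        with pytest.raises(ValueError, match="k"):
            ba.crossval_metrics(fm, np.arange(5.0) + 30, k=6)


class TestBiasAdjustment:
    def test_perfect_predictions_zero_coefficients(self):
        actual = np.linspace(20, 90, 50)
        alpha, beta = ba.fit_bias_adjustment(actual, actual)
        assert alpha == pytest.approx(0.0, abs=1e-12)
        assert beta == pytest.approx(0.0, abs=1e-10)

    def test_closed_form_on_exact_linear_data(self):
        actual = np.linspace(20, 90, 40)
        predicted = 0.5 * actual + 30.0
        alpha, beta = ba.fit_bias_adjustment(predicted, actual)
        assert alpha == pytest.approx(-0.5, abs=1e-10)
        assert beta == pytest.approx(30.0, abs=1e-8)
        corrected = ba.apply_bias_adjustment(predicted, actual, alpha, beta)
        assert np.allclose(corrected, actual, atol=1e-8)
        assert np.allclose(ba.brainpad(corrected, actual), 0.0, atol=1e-8)

    def test_constant_offset(self):
        actual = np.linspace(20, 90, 40)
        alpha, beta = ba.fit_bias_adjustment(actual + 2.0, actual)
        assert alpha == pytest.approx(0.0, abs=1e-12)
        assert beta == pytest.approx(2.0, abs=1e-10)

    def test_identity_when_coefficients_zero(self):
        pred = np.array([50.0, 60.0])
        out = ba.apply_bias_adjustment(pred, np.array([48.0, 62.0]), 0.0, 0.0)
        assert np.array_equal(out, pred)

    def test_zero_age_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ba.fit_bias_adjustment(np.array([1.0, 2, 3]), np.full(3, 60.0))

    def test_training_residual_identities(self):
        # OLS orthogonality: mean corrected PAD = 0 and corr(PAD, age) = 0
        rng = np.random.default_rng(8)
        actual = rng.uniform(20, 90, 200)
        predicted = 0.6 * actual + 15 + rng.normal(0, 5, 200)
        alpha, beta = ba.fit_bias_adjustment(predicted, actual)
        pad = ba.brainpad(ba.apply_bias_adjustment(predicted, actual, alpha, beta), actual)
        assert abs(pad.mean()) < 1e-8
        assert abs(np.corrcoef(pad, actual)[0, 1]) < 1e-8


class TestBrainpadAndEvaluate:
    def test_sign_convention(self):
        assert ba.brainpad(np.array([65.0]), np.array([60.0]))[0] == 5.0
        assert ba.brainpad(np.array([55.0]), np.array([60.0]))[0] == -5.0

    def test_perfect_metrics(self):
        actual = np.linspace(30, 70, 20)
        m = ba.evaluate(actual, actual)
        assert (m.mae, m.rmse, m.mean_pad) == (0.0, 0.0, 0.0)
        assert m.r2 == 1.0

    def test_alternating_errors(self):
        actual = np.array([50.0, 60.0, 70.0, 80.0])
        predicted = actual + np.array([2.0, -2.0, 2.0, -2.0])
        m = ba.evaluate(predicted, actual)
        assert m.mae == pytest.approx(2.0)
        assert m.rmse == pytest.approx(2.0)
        assert m.mean_pad == pytest.approx(0.0)

    def test_constant_predictor_r2_zero(self):
        actual = np.array([40.0, 50.0, 60.0])
        m = ba.evaluate(np.full(3, actual.mean()), actual)
        assert m.r2 == pytest.approx(0.0)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="2"):
            ba.evaluate(np.array([50.0]), np.array([52.0]))

    def test_metrics_invariant_to_ordering(self):
        rng = np.random.default_rng(9)
        actual = rng.uniform(30, 80, 50)
        predicted = actual + rng.normal(0, 3, 50)
        perm = rng.permutation(50)
        m1 = ba.evaluate(predicted, actual)
        m2 = ba.evaluate(predicted[perm], actual[perm])
        assert m1.mae == pytest.approx(m2.mae)
        assert m1.rmse == pytest.approx(m2.rmse)
        assert m1.r2 == pytest.approx(m2.r2)
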
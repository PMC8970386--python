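import warnings

import numpy as np
import pytest

from prealpha import (
    CohortSpec,
    calibrate_index_scale,
    classify_recording,
    compute_index,
    generate_cohort_records,
    ga_select_features,
    train_model,
    train_svm,
)
from prealpha.classifier import (
    ClassifierModel,
    IndexResult,
    _cv_auc,
    _make_folds,
    extract_record_spectra,
    load_model_set,
    save_model_set,
)
from prealpha.config import GAConfig, PipelineConfig
from prealpha.errors import AgeRequiredError, CalibrationError, PooledFallbackWarning
from prealpha.feature_model import CoreFeatureVector, PCABasis

from _oracles import exhaustive_mask_search


def _labels(n):
    return ["DLB" if i < n // 2 else "AD" for i in range(n)]


def _separable(n=20, d=4, seed=0, signal=3.0):
    g = np.random.default_rng(seed)
    X = g.standard_normal((n, d))
    y = _labels(n)
    shift = np.zeros(d)
    shift[:2] = signal
    X[: n // 2] += shift
    ages = g.uniform(60, 90, n)
    return X, ages, y


class TestSvmFit:
    def test_separable_set_fit_perfectly(self):
        X, ages, y = _separable()
        fit = train_svm(X, ages, y)
        raw = (
            X @ fit["beta_features"]
            + fit["beta_age1"] * ages
            + fit["beta_age2"] * ages**2
            + fit["rho"]
        )
        pred = np.where(raw >= 0, "DLB", "AD")
        assert (pred == np.array(y)).all()

    def test_destandardized_formula_matches_decision_function(self):
        from sklearn.svm import SVC

        X, ages, y = _separable(seed=1, signal=1.0)
        fit = train_svm(X, ages, y)
        design = np.column_stack([X, ages, ages**2])
        mu, sd = fit["mu"], fit["sd"]
        svc = SVC(kernel="linear", C=1.0)
        svc.fit((design - mu) / sd, (np.array(y) == "DLB").astype(int))
        native = svc.decision_function((design - mu) / sd)
        explicit = (
            X @ fit["beta_features"]
            + fit["beta_age1"] * ages
            + fit["beta_age2"] * ages**2
            + fit["rho"]
        )
        assert np.abs(native - explicit).max() < 1e-8

    def test_label_flip_negates_raw_index(self):
        X, ages, y = _separable(seed=2, signal=1.0)
        flipped = ["AD" if lab == "DLB" else "DLB" for lab in y]
        f1 = train_svm(X, ages, y)
        f2 = train_svm(X, ages, flipped)
        r1 = X @ f1["beta_features"] + f1["beta_age1"] * ages + f1["beta_age2"] * ages**2 + f1["rho"]
        r2 = X @ f2["beta_features"] + f2["beta_age1"] * ages + f2["beta_age2"] * ages**2 + f2["rho"]
        # symmetry holds up to the SMO solver's convergence tolerance
        np.testing.assert_allclose(r1, -r2, atol=5e-3)

    def test_zero_variance_feature_dropped(self):
        X, ages, y = _separable(seed=3)
        X[:, 2] = 5.0
        fit = train_svm(X, ages, y)
        assert fit["beta_features"][2] == 0.0


class TestCalibration:
    def test_ad_cohort_scaled_sd_is_one(self, rng):
        raw = rng.standard_normal(30)
        y = _labels(30)
        raw[:15] += 2
        c_star, s_ad = calibrate_index_scale(raw, y)
        scaled = (raw - c_star) / s_ad
        assert np.std(scaled[15:], ddof=1) == pytest.approx(1.0)

    def test_scaled_cutoff_sits_at_zero(self, rng):
        raw = rng.standard_normal(30)
        raw[:15] += 2
        y = _labels(30)
        c_star, s_ad = calibrate_index_scale(raw, y)
        scaled = (raw - c_star) / s_ad
        c2, _ = calibrate_index_scale(scaled, y)
        assert c2 == pytest.approx(0.0, abs=1e-12)

    def test_small_example_separates_at_midgap(self):
        raw = np.array([2.0, 3.0, 4.0, 0.0, 1.0])
        y = ["DLB", "DLB", "DLB", "AD", "AD"]
        c_star, s_ad = calibrate_index_scale(raw, y)
        assert 1.0 < c_star < 2.0
        scaled = (raw - c_star) / s_ad
        assert all(s >= 0 for s in scaled[:3])
        assert all(s < 0 for s in scaled[3:])

    def test_zero_spread_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_index_scale([1.0, 2.0, 0.5, 0.5], ["DLB", "DLB", "AD", "AD"])


class TestIndexRule:
    @staticmethod
    def _dummy_model(cutoff=0.0, s_ad=1.0, d=4):
        basis = PCABasis(
            loadings=np.zeros((2, 2, 180)),
            means=np.zeros((2, 180)),
            ranking_auc=np.full((2, 2), 0.5),
            selected=np.zeros((2, 2), dtype=int),
        )
        return ClassifierModel(
            gender="pooled",
            beta=np.zeros(d),
            beta_age1=0.0,
            beta_age2=0.0,
            rho=0.0,
            feature_mask=np.zeros(d, dtype=bool),
            cutoff=cutoff,
            s_ad=s_ad,
            basis=basis,
        )

    def test_zero_index_classified_dlb(self):
        res = IndexResult.from_index(0.0)
        assert res.classification == "DLB"

    def test_negative_index_classified_ad(self):
        assert IndexResult.from_index(-0.3).classification == "AD"

    def test_age_required(self):
        model = self._dummy_model()
        core = CoreFeatureVector(C=np.zeros(4), age=None, gender="M")
        with pytest.raises(AgeRequiredError):
            compute_index(core, model)

    def test_serialized_formula_reproduces_prediction(self, rng):
        model = self._dummy_model(cutoff=0.5, s_ad=2.0)
        model.beta = rng.standard_normal(4)
        model.beta_age1 = 0.01
        model.beta_age2 = -1e-4
        model.rho = 0.3
        core = CoreFeatureVector(C=rng.standard_normal(4), age=77.0, gender="F")
        res = compute_index(core, model)
        a = 77.0
        explicit = (
            core.C @ model.beta + 0.01 * a - 1e-4 * a * a + 0.3 - 0.5
        ) / 2.0
        assert abs(res.index - explicit) < 1e-8


class TestGASelection:
    def test_toy_space_matches_exhaustive_search(self):
        """GA finds the global optimum over all 255 masks of 8 features."""
        g = np.random.default_rng(5)
        n, d = 24, 8
        y = _labels(n)
        X = g.standard_normal((n, d))
        X[: n // 2, [1, 4]] += 1.5
        ages = g.uniform(60, 90, n)
        # per-bit mutation scaled up so ~1 bit flips per child on 8 bits
        ga = GAConfig(
            population=40, generations=30, cv_folds=3, parsimony=0.01,
            mutation_p=0.12,
        )
        rng_ga = np.random.default_rng(11)
        yb = (np.array(y) == "DLB").astype(int)
        folds = _make_folds(yb, ga.cv_folds, int(rng_ga.integers(2**31)))
        mask = ga_select_features(
            X, ages, y, ga=ga, rng=np.random.default_rng(11)
        )

        def fitness(m):
            return _cv_auc(X, ages, yb, m, 1.0, folds) - ga.parsimony * m.sum() / d

        _, best_fit = exhaustive_mask_search(fitness, d)
        assert fitness(mask) == pytest.approx(best_fit, abs=1e-12)

    def test_planted_informative_features_recovered(self):
        """Three jointly informative features among 380 are selected."""
        d, n = 380, 50
        informative = [7, 120, 333]
        hits = np.zeros(3)
        runs = 5
        for seed in range(runs):
            g = np.random.default_rng(100 + seed)
            y = _labels(n)
            yv = np.array([lab == "DLB" for lab in y], dtype=float)
            X = g.standard_normal((n, d))
            for f in informative:
                X[:, f] += 0.9 * (2 * yv - 1) + 0.3 * g.standard_normal(n)
            ages = g.uniform(60, 90, n)
            mask = ga_select_features(
                X,
                ages,
                y,
                ga=GAConfig(
                    population=30, generations=40, cv_folds=3, parsimony=0.02
                ),
                rng=np.random.default_rng(seed),
            )
            hits += mask[informative]
        assert (hits / runs >= 0.9).all()

    def test_deterministic_given_seed(self):
        X, ages, y = _separable(n=16, d=12, seed=6, signal=1.0)
        ga = GAConfig(population=10, generations=4)
        m1 = ga_select_features(X, ages, y, ga=ga, rng=np.random.default_rng(3))
        m2 = ga_select_features(X, ages, y, ga=ga, rng=np.random.default_rng(3))
        np.testing.assert_array_equal(m1, m2)


@pytest.fixture(scope="module")
def small_cohort():
    recs, _ = generate_cohort_records(
        CohortSpec(n_dlb=6, n_ad=6, separation=1.0, seed=123)
    )
    cfg = PipelineConfig(ga=GAConfig(population=8, generations=3), seed=5)
    return [
        extract_record_spectra(r, cfg, label=r.meta["group"]) for r in recs
    ], cfg


class TestTrainModel:
    def test_small_cohort_trains_and_classifies(self, small_cohort):
        cohort, cfg = small_cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ms = train_model(cohort, cfg)
        for rec in cohort:
            res = classify_recording(rec, ms)
            assert np.isfinite(res.index)
            assert res.classification in ("DLB", "AD")

    def test_training_deterministic(self, small_cohort):
        cohort, cfg = small_cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m1 = train_model(cohort, cfg)
            m2 = train_model(cohort, cfg)
        for g in m1.models:
            np.testing.assert_array_equal(m1.models[g].beta, m2.models[g].beta)
            np.testing.assert_array_equal(
                m1.models[g].feature_mask, m2.models[g].feature_mask
            )
            assert m1.models[g].cutoff == m2.models[g].cutoff

    def test_single_gender_cohort_falls_back_to_pooled(self, small_cohort):
        cohort, cfg = small_cohort
        from dataclasses import replace as dc_replace

        mono = [
            dc_replace(rec, gender="M") if hasattr(rec, "gender") else rec
            for rec in cohort
        ]
        for rec in mono:
            rec.gender = "M"
        with pytest.warns(PooledFallbackWarning):
            ms = train_model(mono, cfg)
        assert "pooled" in ms.models or "M" in ms.models

    def test_model_round_trip(self, small_cohort, tmp_path):
        cohort, cfg = small_cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ms = train_model(cohort, cfg)
        save_model_set(ms, tmp_path / "model.npz")
        loaded = load_model_set(tmp_path / "model.npz")
        for rec in cohort[:4]:
            a = classify_recording(rec, ms)
            b = classify_recording(rec, loaded)
            assert a.index == pytest.approx(b.index, abs=1e-12)
            assert a.classification == b.classification
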
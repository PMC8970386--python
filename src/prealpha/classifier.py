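"""Gender-specific linear classifier: GA feature selection, linear SVM,
age terms and the calibrated diagnostic index.

The index of a recording with core features C_pa and age A (years) is

    I_raw = sum_pa C_pa * beta_pa + beta1A * A + beta2A * A^2 + rho

where the coefficients come from a linear SVM trained on a feature
subset chosen by a genetic algorithm (fitness = cross-validated AUC with
a parsimony penalty).  The raw index is then affinely rescaled so that
the optimal training cutoff sits at 0 and one unit equals one standard
deviation of the AD training cohort:

    I = (I_raw - c*) / s_AD,    classification DLB  iff  I >= 0.

Separate models are trained for men and women; a stratum too small to
train falls back to a pooled model with a warning.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .config import GAConfig, PipelineConfig
from .errors import (
    AgeRequiredError,
    CalibrationError,
    PooledFallbackWarning,
)
from .evaluation import roc_auc
from .feature_model import (
    POSITIVE_LABEL,
    CoreFeatureVector,
    PCABasis,
    fit_basis,
    project_core_features,
)
from .io_eeg import EEGRecord, apply_average_reference
from .preprocess import bandpass_filter, extract_epoch, segment_epoch
from .spectral import (
    SegmentSpectra,
    compute_covariances,
    compute_segment_spectra,
    robust_aggregate,
)

logger = logging.getLogger(__name__)

GENDERS = ("M", "F")
POOLED = "pooled"


# ---------------------------------------------------------------------------
# extraction front end


@dataclass
class ExtractedRecording:
    """Segment spectra of one recording plus the covariates the model needs."""

    spectra: SegmentSpectra
    subject_id: str
    age: float | None
    gender: str | None
    label: str | None = None  # clinical diagnosis, present for training


def extract_record_spectra(
    record: EEGRecord, config: PipelineConfig = PipelineConfig(), label=None
) -> ExtractedRecording:
    """Average-reference, filter, epoch, segment and Fourier-transform."""
    rec = record.validate()
    if rec.reference != "average":
        rec = apply_average_reference(rec)
    rec = bandpass_filter(
        rec,
        low=config.filter_low_hz,
        high=config.filter_high_hz,
        order=config.filter_order,
        zero_phase=config.filter_zero_phase,
    )
    epoch = extract_epoch(
        rec, duration=config.epoch_duration_s, start=config.epoch_start_s
    )
    segments = segment_epoch(
        epoch, length=config.segment_length_s, step=config.segment_step_s
    )
    spectra = compute_segment_spectra(segments)
    return ExtractedRecording(
        spectra=spectra,
        subject_id=record.subject_id,
        age=record.subject_age,
        gender=record.subject_gender,
        label=label,
    )


# ---------------------------------------------------------------------------
# model containers


@dataclass
class ClassifierModel:
    """A trained, calibrated index for one gender stratum."""

    gender: str
    beta: np.ndarray  # (n_core,) zero where the GA dropped the feature
    beta_age1: float
    beta_age2: float
    rho: float
    feature_mask: np.ndarray  # (n_core,) bool
    cutoff: float  # c*, raw-index units
    s_ad: float  # SD of the AD training cohort's raw indices
    basis: PCABasis
    provenance: dict = field(default_factory=dict)

    def raw_index(self, core: CoreFeatureVector) -> float:
        if core.age is None:
            raise AgeRequiredError("the index formula requires the subject's age")
        a = float(core.age)
        return float(
            core.C @ self.beta + self.beta_age1 * a + self.beta_age2 * a * a + self.rho
        )

    def scaled_index(self, core: CoreFeatureVector) -> float:
        return (self.raw_index(core) - self.cutoff) / self.s_ad


@dataclass(frozen=True)
class IndexResult:
    """Scaled index (AD-SD units) and the threshold-rule classification."""

    index: float
    classification: str  # DLB iff index >= 0

    @staticmethod
    def from_index(index: float) -> "IndexResult":
        return IndexResult(
            index=index, classification="DLB" if index >= 0 else "AD"
        )


def compute_index(core: CoreFeatureVector, model: ClassifierModel) -> IndexResult:
    """Evaluate the calibrated index; DLB iff the scaled index is >= 0."""
    return IndexResult.from_index(model.scaled_index(core))


@dataclass
class ModelSet:
    """Per-gender models with an optional pooled fallback."""

    models: dict
    config: PipelineConfig
    report: dict = field(default_factory=dict)

    def model_for(self, gender: str | None) -> ClassifierModel:
        if gender in self.models:
            return self.models[gender]
        if POOLED in self.models:
            return self.models[POOLED]
        raise KeyError(f"no model for gender {gender!r} and no pooled fallback")


# ---------------------------------------------------------------------------
# SVM fit with de-standardized coefficients


def _design(features: np.ndarray, ages: np.ndarray) -> np.ndarray:
    a = np.asarray(ages, dtype=float)
    return np.column_stack([features, a, a * a])


def train_svm(
    features: np.ndarray,
    ages: np.ndarray,
    labels,
    svm_c: float = 1.0,
) -> dict:
    """Fit the linear SVM on standardized features + age + age^2.

    Coefficients are de-standardized back to the original feature scale
    so the explicit index formula reproduces the SVM decision value
    exactly.  Zero-variance columns are dropped (coefficient 0, logged).
    """
    y = (np.asarray(labels) == POSITIVE_LABEL).astype(int)
    if y.all() or not y.any():
        raise ValueError("training requires both classes")
    X = _design(features, ages)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    live = sd > 0
    if not live.all():
        logger.info("dropping %d zero-variance column(s)", int((~live).sum()))
    Z = (X[:, live] - mu[live]) / sd[live]
    svc = SVC(kernel="linear", C=svm_c)
    svc.fit(Z, y)
    w_std = svc.coef_.ravel()
    b_std = float(svc.intercept_[0])
    w = np.zeros(X.shape[1])
    w[live] = w_std / sd[live]
    rho = b_std - float((w_std * (mu[live] / sd[live])).sum())
    return {
        "beta_features": w[:-2],
        "beta_age1": float(w[-2]),
        "beta_age2": float(w[-1]),
        "rho": rho,
        "mu": mu,
        "sd": sd,
    }


# ---------------------------------------------------------------------------
# GA feature-subset search


def _cv_auc(
    features: np.ndarray,
    ages: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray,
    svm_c: float,
    folds: list[tuple[np.ndarray, np.ndarray]],
) -> float:
    """Pooled out-of-fold decision-value AUC of the masked linear SVM."""
    X = _design(features[:, mask], ages)
    scores = np.empty(len(y))
    for tr, va in folds:
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Ztr = (X[tr] - mu) / sd
        Zva = (X[va] - mu) / sd
        svc = SVC(kernel="linear", C=svm_c)
        svc.fit(Ztr, y[tr])
        scores[va] = svc.decision_function(Zva)
    labels = np.where(y == 1, "DLB", "AD")
    return roc_auc(scores, labels)


def _make_folds(y: np.ndarray, n_folds: int, seed: int):
    n_min = min(int(y.sum()), int(len(y) - y.sum()))
    k = max(2, min(n_folds, n_min))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    return list(skf.split(np.zeros(len(y)), y))


def ga_select_features(
    features: np.ndarray,
    ages: np.ndarray,
    labels,
    ga: GAConfig = GAConfig(),
    svm_c: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Binary feature mask maximizing CV-AUC minus a parsimony penalty.

    Steady generational GA: tournament selection, uniform crossover,
    per-bit mutation, elitism.  An all-zero candidate is repaired by
    activating the single feature with the best univariate folded AUC.
    Fully deterministic given the generator.
    """
    rng = rng or np.random.default_rng(0)
    y = (np.asarray(labels) == POSITIVE_LABEL).astype(int)
    n, d = features.shape
    n_min = min(int(y.sum()), int(len(y) - y.sum()))
    if n_min < 10:
        warnings.warn(
            f"only {n_min} subjects in the smaller class; GA selection is "
            "recommended with >= 10 per class",
            UserWarning,
        )
    folds = _make_folds(y, ga.cv_folds, int(rng.integers(2**31)))

    # univariate folded AUCs, used only for all-zero-mask repair
    from .feature_model import _auc_columns

    uni = _auc_columns(features, y.astype(bool))
    best_single = int(np.argmax(np.maximum(uni, 1 - uni)))

    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        if not mask.any():
            mask = mask.copy()
            mask[best_single] = True
        key = np.packbits(mask).tobytes()
        if key not in cache:
            auc = _cv_auc(features, ages, y, mask, svm_c, folds)
            cache[key] = auc - ga.parsimony * mask.sum() / d
        return cache[key]

    # half the initial population dense, half sparse, for diversity
    pop = [rng.random(d) < (0.5 if i % 2 == 0 else 0.1) for i in range(ga.population)]
    for i, m in enumerate(pop):
        if not m.any():
            m = m.copy()
            m[best_single] = True
            pop[i] = m
    fits = np.array([fitness(m) for m in pop])

    for _ in range(ga.generations):
        order = np.argsort(-fits, kind="stable")
        new_pop = [pop[order[e]].copy() for e in range(min(ga.elitism, len(pop)))]
        while len(new_pop) < ga.population:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, len(pop), ga.tournament)
                parents.append(pop[contenders[np.argmax(fits[contenders])]])
            take = rng.random(d) < ga.crossover_p
            child = np.where(take, parents[0], parents[1])
            child ^= rng.random(d) < ga.mutation_p
            if not child.any():
                child[best_single] = True
            new_pop.append(child)
        pop = new_pop
        fits = np.array([fitness(m) for m in pop])

    best = pop[int(np.argmax(fits))].copy()
    if not best.any():
        best[best_single] = True
    return best


# ---------------------------------------------------------------------------
# index calibration


def calibrate_index_scale(raw_indices, labels) -> tuple[float, float]:
    """Optimal raw cutoff c* (Youden's J) and the AD-cohort SD s_AD.

    Candidate cutoffs are midpoints between consecutive sorted raw
    indices plus one candidate below the minimum and one above the
    maximum; prediction rule is DLB iff raw >= c.  Ties in J are broken
    toward the candidate closest to the midpoint of the class medians.
    """
    raw = np.asarray(raw_indices, dtype=float)
    y = np.asarray(labels)
    pos = y == POSITIVE_LABEL
    neg = ~pos
    if not pos.any() or not neg.any():
        raise ValueError("calibration requires both classes")
    s_ad = float(np.std(raw[neg], ddof=1)) if neg.sum() > 1 else 0.0
    if s_ad <= 0:
        raise CalibrationError("AD training indices have zero spread")
    u = np.unique(raw)
    cands = np.concatenate([[u[0] - 1.0], (u[:-1] + u[1:]) / 2, [u[-1] + 1.0]])
    sens = np.array([(raw[pos] >= c).mean() for c in cands])
    spec = np.array([(raw[neg] < c).mean() for c in cands])
    j = sens + spec - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)
    anchor = (np.median(raw[pos]) + np.median(raw[neg])) / 2
    c_star = float(cands[best[np.argmin(np.abs(cands[best] - anchor))]])
    return c_star, s_ad


# ---------------------------------------------------------------------------
# training pipeline


def _subject_core_matrix(
    cohort: list[ExtractedRecording], basis: PCABasis, estimator: str
) -> tuple[np.ndarray, np.ndarray]:
    cores = []
    for rec in cohort:
        tensor = compute_covariances(rec.spectra)
        cv = project_core_features(
            tensor,
            basis,
            age=rec.age,
            gender=rec.gender,
            subject_id=rec.subject_id,
            estimator=estimator,
        )
        cores.append(cv)
    C = np.stack([c.C for c in cores])
    ages = np.array([c.age for c in cores], dtype=float)
    return C, ages


def _train_stratum(
    cohort: list[ExtractedRecording],
    config: PipelineConfig,
    gender_tag: str,
    seed: int,
) -> tuple[ClassifierModel, dict]:
    labels = [rec.label for rec in cohort]
    base = [
        robust_aggregate(
            compute_covariances(rec.spectra),
            estimator=config.estimator,
            subject_id=rec.subject_id,
            age=rec.age,
            gender=rec.gender,
        )
        for rec in cohort
    ]
    n_pos = sum(lab == POSITIVE_LABEL for lab in labels)
    basis = fit_basis(
        base,
        labels,
        selection=config.selection,
        fitted_on={
            "gender": gender_tag,
            "n_dlb": n_pos,
            "n_ad": len(labels) - n_pos,
            "seed": seed,
        },
    )
    C, ages = _subject_core_matrix(cohort, basis, config.estimator)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xFEA7)))
    mask = ga_select_features(
        C, ages, labels, ga=config.ga, svm_c=config.svm_c, rng=rng
    )
    fit = train_svm(C[:, mask], ages, labels, svm_c=config.svm_c)
    beta = np.zeros(C.shape[1])
    beta[mask] = fit["beta_features"]
    raw = C @ beta + fit["beta_age1"] * ages + fit["beta_age2"] * ages**2 + fit["rho"]
    cutoff, s_ad = calibrate_index_scale(raw, labels)
    y = np.asarray(labels)
    cv_auc = _cv_auc(
        C,
        ages,
        (y == POSITIVE_LABEL).astype(int),
        mask,
        config.svm_c,
        _make_folds((y == POSITIVE_LABEL).astype(int), config.ga.cv_folds, seed),
    )
    model = ClassifierModel(
        gender=gender_tag,
        beta=beta,
        beta_age1=fit["beta_age1"],
        beta_age2=fit["beta_age2"],
        rho=fit["rho"],
        feature_mask=mask,
        cutoff=cutoff,
        s_ad=s_ad,
        basis=basis,
        provenance={"seed": seed, "config": config.digest()},
    )
    report = {
        "gender": gender_tag,
        "n_dlb": int(n_pos),
        "n_ad": int(len(labels) - n_pos),
        "mask_size": int(mask.sum()),
        "cv_auc": float(cv_auc),
        "seed": seed,
    }
    return model, report


def train_model(
    cohort: list[ExtractedRecording], config: PipelineConfig = PipelineConfig()
) -> ModelSet:
    """Train gender-specific models (pooled fallback for small strata).

    Every subject needs a label, age and gender.  A gender stratum with
    fewer than ``config.min_per_class`` subjects in either class is not
    trained separately; classification for that gender uses the pooled
    model and a :class:`PooledFallbackWarning` is issued.
    """
    for rec in cohort:
        if rec.label is None:
            raise ValueError(f"subject {rec.subject_id!r} has no diagnosis label")
        if rec.age is None:
            raise AgeRequiredError(f"subject {rec.subject_id!r} has no age")
    models: dict = {}
    reports = []
    need_pooled = False
    for gi, gender in enumerate(GENDERS):
        stratum = [r for r in cohort if r.gender == gender]
        labels = [r.label for r in stratum]
        n_pos = sum(lab == POSITIVE_LABEL for lab in labels)
        n_neg = len(labels) - n_pos
        if min(n_pos, n_neg) < config.min_per_class:
            warnings.warn(
                f"gender {gender}: {n_pos} DLB / {n_neg} AD below the "
                f"per-class minimum {config.min_per_class}; using pooled model",
                PooledFallbackWarning,
            )
            need_pooled = True
            continue
        seed = int(
            np.random.SeedSequence((config.seed, gi)).generate_state(1)[0] % (2**31)
        )
        models[gender], rep = _train_stratum(stratum, config, gender, seed)
        reports.append(rep)
    if need_pooled or not models:
        seed = int(
            np.random.SeedSequence((config.seed, 99)).generate_state(1)[0] % (2**31)
        )
        models[POOLED], rep = _train_stratum(cohort, config, POOLED, seed)
        reports.append(rep)
    return ModelSet(models=models, config=config, report={"strata": reports})


def classify_recording(
    rec: ExtractedRecording, model_set: ModelSet
) -> IndexResult:
    """Index and classification of an extracted recording."""
    model = model_set.model_for(rec.gender)
    tensor = compute_covariances(rec.spectra)
    core = project_core_features(
        tensor,
        model.basis,
        age=rec.age,
        gender=rec.gender,
        subject_id=rec.subject_id,
        estimator=model_set.config.estimator,
    )
    return compute_index(core, model)


# ---------------------------------------------------------------------------
# serialization


def save_model_set(model_set: ModelSet, path) -> None:
    """Single-file versioned archive of all strata (npz)."""
    payload = {"version": np.array([1])}
    meta = {
        "config": model_set.config.as_dict(),
        "report": model_set.report,
        "genders": list(model_set.models),
    }
    payload["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    for g, m in model_set.models.items():
        payload[f"{g}_beta"] = m.beta
        payload[f"{g}_age"] = np.array([m.beta_age1, m.beta_age2, m.rho])
        payload[f"{g}_mask"] = m.feature_mask
        payload[f"{g}_calib"] = np.array([m.cutoff, m.s_ad])
        payload[f"{g}_loadings"] = m.basis.loadings
        payload[f"{g}_means"] = m.basis.means
        payload[f"{g}_auc"] = m.basis.ranking_auc
        payload[f"{g}_sel"] = m.basis.selected
    np.savez_compressed(path, **payload)


def load_model_set(path) -> ModelSet:
    from .config import GAConfig, PipelineConfig

    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        cfg_d = meta["config"]
        ga = GAConfig(**cfg_d.pop("ga"))
        config = PipelineConfig(ga=ga, **cfg_d)
        models = {}
        for g in meta["genders"]:
            age = z[f"{g}_age"]
            calib = z[f"{g}_calib"]
            basis = PCABasis(
                loadings=z[f"{g}_loadings"],
                means=z[f"{g}_means"],
                ranking_auc=z[f"{g}_auc"],
                selected=z[f"{g}_sel"],
            )
            models[g] = ClassifierModel(
                gender=g,
                beta=z[f"{g}_beta"],
                beta_age1=float(age[0]),
                beta_age2=float(age[1]),
                rho=float(age[2]),
                feature_mask=z[f"{g}_mask"].astype(bool),
                cutoff=float(calib[0]),
                s_ad=float(calib[1]),
                basis=basis,
            )
    return ModelSet(models=models, config=config, report=meta["report"])
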
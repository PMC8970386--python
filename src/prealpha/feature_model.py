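"""Per-pair PCA, AUC-based component ranking and core-feature projection.

The 34,200 base features decompose into 190 per-pair blocks of 180 reals
(90 frequencies x re/im).  For each block a PCA is fitted across training
subjects; every principal component is then scored by how well its
subject scores separate DLB from AD (area under the ROC curve, folded to
max(A, 1-A) since orientation is arbitrary), and the two most
discriminative components per pair are retained: 190 x 2 = 380 core
features.

A recording's core feature C_pa is the robust across-segment expectation
of the inner product between its per-segment covariance block (centered
with the training means) and the retained loading vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .errors import ProjectionError, RankingError
from .spectral import (
    BaseFeatureVector,
    CovarianceTensor,
    N_FREQ_BINS,
    _aggregate,
    n_pairs,
)

logger = logging.getLogger(__name__)

#: Positive class label throughout the package.
POSITIVE_LABEL = "DLB"
NEGATIVE_LABEL = "AD"

N_COMPONENTS_PER_PAIR = 2
BLOCK_DIM = 2 * N_FREQ_BINS  # 180


@dataclass
class PCABasis:
    """Selected per-pair loadings defining the 380-dimension core space."""

    loadings: np.ndarray  # (n_pairs, 2, 180), unit-norm rows
    means: np.ndarray  # (n_pairs, 180) training means used for centering
    ranking_auc: np.ndarray  # (n_pairs, 2) folded AUC of each kept component
    selected: np.ndarray  # (n_pairs, 2) variance-rank index of each kept comp
    fitted_on: dict = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_core_features(self) -> int:
        return self.loadings.shape[0] * self.loadings.shape[1]


@dataclass
class CoreFeatureVector:
    """The 380 projected features of one recording, with covariates."""

    C: np.ndarray  # (380,)
    age: float | None
    gender: str | None
    subject_id: str = ""


def _stack_blocks(vectors: list[BaseFeatureVector]) -> np.ndarray:
    """(n_subjects, n_pairs, 180) array from subject base-feature vectors."""
    X = np.stack([v.values for v in vectors])
    n_p = X.shape[1] // BLOCK_DIM
    return X.reshape(len(vectors), n_p, BLOCK_DIM)


def fit_pca_per_pair(
    training: list[BaseFeatureVector],
) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
    """Fit a covariance-PCA on each pair's 180-dim block across subjects.

    Returns ``(components, explained_var, means)`` where ``components[p]``
    is ``(k_p, 180)`` orthonormal rows ordered by explained variance,
    ``k_p = min(n_subjects - 1, 180)`` minus any zero-variance directions,
    and ``means`` is the ``(n_pairs, 180)`` per-pair training mean.
    Blocks are centered but not variance-scaled: the downstream SVM
    standardization absorbs scale.
    """
    if len(training) < 2:
        raise ValueError("PCA requires at least 2 training subjects")
    B = _stack_blocks(training).astype(np.float64)
    n, p, d = B.shape
    means = B.mean(axis=0)
    components: list[np.ndarray] = []
    explained: list[np.ndarray] = []
    for j in range(p):
        Xc = B[:, j, :] - means[j]
        # SVD of the centered block; right singular vectors = loadings
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        var = s**2 / max(n - 1, 1)
        nz = var > max(var.max(), 0.0) * 1e-12
        if not nz.any():
            logger.info("pair %d has a zero-variance block; no components", j)
            components.append(np.zeros((0, d)))
            explained.append(np.zeros(0))
            continue
        components.append(Vt[nz])
        explained.append(var[nz])
    return components, explained, means


def _labels_to_bool(labels) -> np.ndarray:
    y = np.asarray(labels)
    pos = y == POSITIVE_LABEL
    neg = y == NEGATIVE_LABEL
    if not (pos | neg).all():
        bad = sorted(set(y[~(pos | neg)]))
        raise ValueError(f"unknown labels {bad}; expected DLB/AD")
    return pos


def _auc_columns(scores: np.ndarray, positive: np.ndarray) -> np.ndarray:
    """Mann-Whitney AUC of each column of ``scores`` (ties count 1/2)."""
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    ranks = _stats.rankdata(scores, axis=0)
    r_pos = ranks[positive].sum(axis=0)
    return (r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def rank_components_by_auc(
    scores: np.ndarray, labels
) -> tuple[np.ndarray, np.ndarray]:
    """Folded AUC per component and the descending ranking order.

    ``scores`` is ``(n_subjects, n_components)``.  AUCs are folded as
    ``max(A, 1-A)`` because component orientation carries no information;
    ties in AUC are broken by explained-variance order (i.e. by column
    index, stable sort).
    """
    positive = _labels_to_bool(labels)
    if positive.all() or not positive.any():
        raise RankingError("component ranking requires both classes")
    auc = _auc_columns(scores, positive)
    folded = np.maximum(auc, 1.0 - auc)
    order = np.argsort(-folded, kind="stable")
    return folded, order


def select_top_components(
    components: list[np.ndarray],
    explained: list[np.ndarray],
    means: np.ndarray,
    training: list[BaseFeatureVector],
    labels,
    selection: str = "auc",
    fitted_on: dict | None = None,
) -> PCABasis:
    """Retain the two most discriminative components of every pair.

    ``selection="auc"`` keeps each pair's two best folded-AUC components
    (``"variance"`` keeps the first two by explained variance instead).
    Pairs with fewer than two valid components are padded with
    zero loadings (logged); their core features are structurally zero.
    """
    B = _stack_blocks(training)
    n_p = len(components)
    loadings = np.zeros((n_p, N_COMPONENTS_PER_PAIR, BLOCK_DIM))
    aucs = np.full((n_p, N_COMPONENTS_PER_PAIR), 0.5)
    chosen = np.zeros((n_p, N_COMPONENTS_PER_PAIR), dtype=int)
    for j in range(n_p):
        comp = components[j]
        if comp.shape[0] == 0:
            logger.info("pair %d padded with zero loadings", j)
            continue
        scores = (B[:, j, :] - means[j]) @ comp.T
        if selection == "auc":
            folded, order = rank_components_by_auc(scores, labels)
        elif selection == "variance":
            folded = np.full(comp.shape[0], 0.5)
            order = np.arange(comp.shape[0])
        else:
            raise ValueError("selection must be 'auc' or 'variance'")
        keep = order[:N_COMPONENTS_PER_PAIR]
        for a, idx in enumerate(keep):
            loadings[j, a] = comp[idx]
            aucs[j, a] = folded[idx] if selection == "auc" else np.nan
            chosen[j, a] = idx
        if comp.shape[0] < N_COMPONENTS_PER_PAIR:
            logger.info("pair %d has only %d component(s); padded", j, comp.shape[0])
    return PCABasis(
        loadings=loadings,
        means=means,
        ranking_auc=aucs,
        selected=chosen,
        fitted_on=dict(fitted_on or {}),
    )


def fit_basis(
    training: list[BaseFeatureVector],
    labels,
    selection: str = "auc",
    fitted_on: dict | None = None,
) -> PCABasis:
    """Full basis fit: per-pair PCA, AUC ranking, top-2 selection."""
    components, explained, means = fit_pca_per_pair(training)
    return select_top_components(
        components, explained, means, training, labels, selection, fitted_on
    )


def project_core_features(
    tensor: CovarianceTensor,
    basis: PCABasis,
    age: float | None = None,
    gender: str | None = None,
    subject_id: str = "",
    estimator: str = "median",
) -> CoreFeatureVector:
    """Project a recording's covariance tensor into the core space.

    Each segment's per-pair block (re/im-interleaved, centered with the
    training means) is projected onto the retained loadings; the robust
    expectation across segments (same estimator as the base-feature
    aggregation) gives the 380 core features.
    """
    n_seg, p, nf = tensor.chi.shape
    if p != basis.n_pairs or 2 * nf != basis.loadings.shape[2]:
        raise ProjectionError(
            f"tensor ({p} pairs x {nf} bins) does not match basis "
            f"({basis.n_pairs} pairs x {basis.loadings.shape[2] // 2} bins)"
        )
    blocks = np.stack([tensor.chi.real, tensor.chi.imag], axis=-1).reshape(
        n_seg, p, 2 * nf
    )
    # single precision here: the across-segment aggregation dominates the
    # runtime and 32-bit resolution is negligible next to segment scatter
    dt = np.float32 if blocks.dtype == np.float32 else np.float64
    centered = blocks - basis.means[None].astype(dt)
    scores = np.einsum("spd,pad->spa", centered, basis.loadings.astype(dt))
    C = _aggregate(scores, estimator).reshape(-1)
    return CoreFeatureVector(C=C, age=age, gender=gender, subject_id=subject_id)


def project_base_vector(vector: BaseFeatureVector, basis: PCABasis) -> np.ndarray:
    """Project a subject-level base vector (no segment expectation)."""
    blocks = vector.values.reshape(basis.n_pairs, BLOCK_DIM)
    centered = blocks - basis.means
    return np.einsum("pd,pad->pa", centered, basis.loadings).reshape(-1)


def save_basis(basis: PCABasis, path) -> None:
    """Serialize a fitted basis (single .npz archive, versioned)."""
    import json

    np.savez_compressed(
        path,
        version=np.array([1]),
        loadings=basis.loadings,
        means=basis.means,
        ranking_auc=basis.ranking_auc,
        selected=basis.selected,
        fitted_on=np.frombuffer(
            json.dumps(basis.fitted_on).encode(), dtype=np.uint8
        ),
    )


def load_basis(path) -> PCABasis:
    import json

    with np.load(path) as z:
        fitted = json.loads(bytes(z["fitted_on"]).decode()) if "fitted_on" in z else {}
        return PCABasis(
            loadings=z["loadings"],
            means=z["means"],
            ranking_auc=z["ranking_auc"],
            selected=z["selected"],
            fitted_on=fitted,
        )
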
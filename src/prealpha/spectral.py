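"""Segment spectra, cross-channel spectral covariances and robust aggregation.

Each 2-s segment is Fourier transformed at its native 0.5 Hz bin spacing;
bins 1..90 (0.5-45 Hz) are retained as 90 complex values sigma_cij per
channel c and segment i.  The full-spectral-resolution covariance between
channels c and k is

    chi_ckij = sigma_cij * conj(sigma_kij)

over the 190 unordered channel pairs of the 19-channel montage (19 auto
pairs, whose covariance is the power spectrum, plus 171 cross pairs).
Aggregating each real and imaginary part across segments with a robust
estimator (marginal median by default) yields the 190 x 90 x 2 = 34,200
base features of a recording; artefact-contaminated segments are
outvoted by the median, which acts as automatic artefact removal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AggregationError, ResolutionError
from .preprocess import SegmentSet

#: Number of retained frequency bins: 0.5, 1.0, ..., 45.0 Hz.
N_FREQ_BINS = 90
FREQ_RESOLUTION_HZ = 0.5
FREQUENCIES_HZ = np.arange(1, N_FREQ_BINS + 1) * FREQ_RESOLUTION_HZ

#: Robust across-segment estimators available for aggregation.
_ESTIMATORS = ("median", "trimmed_mean", "mean")
TRIM_FRACTION = 0.2


def enumerate_pairs(n_channels: int = 19) -> list[tuple[int, int]]:
    """Deterministic ordering of the unordered channel pairs.

    All auto pairs ``(c, c)`` first, in canonical channel order, then the
    cross pairs ``(c, k)`` with ``c < k`` in lexicographic order.  For 19
    channels this gives 19 + 171 = 190 pairs.
    """
    if n_channels < 1:
        raise ValueError("need at least one channel")
    pairs = [(c, c) for c in range(n_channels)]
    pairs += [
        (c, k) for c in range(n_channels) for k in range(c + 1, n_channels)
    ]
    return pairs


def n_pairs(n_channels: int = 19) -> int:
    return n_channels + n_channels * (n_channels - 1) // 2


@dataclass
class SegmentSpectra:
    """Complex DFT coefficients ``sigma[i, c, j]`` at 0.5-45 Hz."""

    sigma: np.ndarray  # (n_segments, n_channels, 90) complex
    sampling_rate: float

    @property
    def n_segments(self) -> int:
        return self.sigma.shape[0]

    @property
    def n_channels(self) -> int:
        return self.sigma.shape[1]


@dataclass
class CovarianceTensor:
    """Spectral covariances ``chi[i, p, j]`` over the ordered pair list."""

    chi: np.ndarray  # (n_segments, n_pairs, 90) complex
    pairs: list[tuple[int, int]]

    @property
    def n_segments(self) -> int:
        return self.chi.shape[0]


@dataclass
class BaseFeatureVector:
    """Robustly aggregated spectral-covariance features of one recording.

    ``values`` holds 190 x 90 x 2 = 34,200 reals ordered as
    (pair, frequency, {real, imaginary}); imaginary slots of auto pairs
    are structural zeros.
    """

    values: np.ndarray  # (34200,) for 19 channels
    subject_id: str = ""
    age: float | None = None
    gender: str | None = None

    def pair_blocks(self, n_channels: int = 19) -> np.ndarray:
        """View as per-pair blocks of 180 reals (frequency-major, re/im)."""
        p = n_pairs(n_channels)
        return self.values.reshape(p, 2 * N_FREQ_BINS)


def compute_segment_spectra(segments: SegmentSet) -> SegmentSpectra:
    """DFT each segment/channel and keep bins 1..90 (0.5-45 Hz).

    Requires 2-s segments sampled so that ``2 * fs`` is an integer number
    of samples: the rectangular-window DFT of a 2-s segment then has an
    exact 0.5 Hz bin spacing and the 90 retained bins land exactly on
    0.5, 1.0, ..., 45 Hz.  Coefficients are scaled by 1/n_samples so
    magnitudes are sampling-rate invariant; the DC bin is discarded.
    """
    fs = segments.sampling_rate
    n_samp = segments.segments.shape[2]
    if segments.segment_length != 2.0 or abs(n_samp - 2 * fs) > 1e-9:
        raise ResolutionError(
            "native 0.5 Hz bins require 2-s segments with integer fs*2 samples"
        )
    if fs < 2 * FREQUENCIES_HZ[-1]:
        raise ResolutionError("sampling rate below Nyquist for the 45 Hz cap")
    spec = np.fft.rfft(segments.segments, axis=2) / n_samp
    sigma = spec[:, :, 1 : N_FREQ_BINS + 1]
    # single precision: halves the memory/time of the covariance tensors
    # while leaving ~7 significant digits, far beyond EEG quantization
    return SegmentSpectra(
        sigma=np.ascontiguousarray(sigma, dtype=np.complex64), sampling_rate=fs
    )


def compute_covariances(spectra: SegmentSpectra) -> CovarianceTensor:
    """Per-segment covariance ``sigma_c * conj(sigma_k)`` for every pair."""
    pairs = enumerate_pairs(spectra.n_channels)
    c_idx = np.array([c for c, _ in pairs])
    k_idx = np.array([k for _, k in pairs])
    chi = spectra.sigma[:, c_idx, :] * np.conj(spectra.sigma[:, k_idx, :])
    # auto covariances are |sigma|^2: force the structural zero imaginary
    # part exactly (FMA contraction otherwise leaves ~1e-9 residues)
    chi[:, : spectra.n_channels, :].imag = 0.0
    return CovarianceTensor(chi=chi, pairs=pairs)


def _aggregate(stack: np.ndarray, estimator: str) -> np.ndarray:
    """Aggregate axis 0 of a real array with the configured estimator."""
    if estimator == "median":
        return np.median(stack, axis=0)
    if estimator == "mean":
        return stack.mean(axis=0)
    if estimator == "trimmed_mean":
        from scipy import stats

        return stats.trim_mean(stack, TRIM_FRACTION, axis=0)
    raise ValueError(f"unknown estimator {estimator!r}; use one of {_ESTIMATORS}")


def robust_aggregate(
    tensor: CovarianceTensor,
    estimator: str = "median",
    subject_id: str = "",
    age: float | None = None,
    gender: str | None = None,
) -> BaseFeatureVector:
    """Aggregate the covariance tensor across segments into base features.

    Real and imaginary parts are aggregated separately (marginal
    estimator).  Requires at least 3 segments; with fewer, a robust
    across-segment estimate is meaningless.
    """
    if tensor.n_segments < 3:
        raise AggregationError(
            f"robust aggregation needs >= 3 segments, got {tensor.n_segments}"
        )
    re = _aggregate(tensor.chi.real, estimator)
    im = _aggregate(tensor.chi.imag, estimator)
    values = np.stack([re, im], axis=-1).reshape(-1)
    return BaseFeatureVector(
        values=values, subject_id=subject_id, age=age, gender=gender
    )


def feature_names(
    channel_labels: tuple[str, ...],
) -> list[str]:
    """Column names ``pair_<c>_<k>_f<freq>_<re|im>`` in feature order."""
    names = []
    for c, k in enumerate_pairs(len(channel_labels)):
        for f in FREQUENCIES_HZ:
            for part in ("re", "im"):
                names.append(
                    f"pair_{channel_labels[c]}_{channel_labels[k]}_f{f:g}_{part}"
                )
    return names
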
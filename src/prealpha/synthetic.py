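"""Seeded synthetic 19-channel EEG cohorts with DLB-like vs AD-like contrast.

The simulator translates the qEEG contrasts that separate the two
dementias into a generative signal model:

* a posterior-dominant narrowband rhythm whose instantaneous frequency
  follows a reflected random walk around the subject's dominant
  frequency — alpha (~9 Hz) for AD-like subjects, slowed "pre-alpha"
  (5.6-7.9 Hz) with greater frequency variability for DLB-like subjects;
* diffuse 1-4 Hz slow activity, stronger in the DLB-like group;
* 1/f (pink) background noise per channel plus a shared volume-conduction
  term so cross-channel covariances carry signal;
* optional blink (frontal, <3 Hz transients) and EMG (temporal, >20 Hz
  bursts) artefacts.

A single separation knob ``lam`` in [0, 1] linearly interpolates the
DLB-like generative parameters between the AD-like means (lam = 0,
identical groups) and the fully separated defaults (lam = 1).  All
draws are reproducible from ``(seed, subject index)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .io_eeg import CANONICAL_CHANNELS, EEGRecord, write_edf

DLB_LIKE = "DLB"
AD_LIKE = "AD"

#: Group generative parameters at full separation (lam = 1).  The
#: dominant-frequency band for DLB-like subjects is the pre-alpha range.
_AD_PARAMS = {
    "freq_mean": 9.0, "freq_sd": 0.5, "freq_clip": (7.0, 11.0),
    "variability_mean": 0.3, "variability_sd": 0.05,
    "slow_gain_mean": 1.0, "slow_gain_sd": 0.1,
}
_DLB_PARAMS = {
    "freq_mean": 6.8, "freq_sd": 0.6, "freq_clip": (5.6, 7.9),
    "variability_mean": 0.8, "variability_sd": 0.1,
    "slow_gain_mean": 1.8, "slow_gain_sd": 0.2,
}

#: Amplitude topography of the dominant rhythm (canonical channel order).
_POSTERIOR = {"O1", "O2", "P3", "P4", "Pz", "T5", "T6"}
_CENTRAL = {"C3", "C4", "Cz", "T3", "T4"}
_RHYTHM_GAIN = np.array(
    [1.0 if c in _POSTERIOR else 0.6 if c in _CENTRAL else 0.35
     for c in CANONICAL_CHANNELS]
)
_FRONTAL_GAIN = np.array(
    [1.0 if c in ("Fp1", "Fp2") else 0.5 if c in ("F3", "F4", "F7", "F8", "Fz")
     else 0.1 for c in CANONICAL_CHANNELS]
)
_TEMPORAL_GAIN = np.array(
    [1.0 if c in ("T3", "T4", "T5", "T6") else 0.6 if c in ("F7", "F8")
     else 0.05 for c in CANONICAL_CHANNELS]
)

RHYTHM_AMP_UV = 15.0
PINK_RMS_UV = 8.0
SLOW_RMS_UV = 4.0
SHARED_MIX = 0.3  # volume-conduction gain of the common pink source


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level generative settings."""

    n_dlb: int
    n_ad: int
    separation: float = 1.0  # lam in [0, 1]
    fs: float = 200.0
    duration: float = 170.0  # seconds; >= 150 required downstream
    seed: int = 0
    artefact_rate: float = 0.0  # events/min, blinks and EMG each
    age_mean: float = 76.5
    age_sd: float = 6.0
    age_range: tuple[float, float] = (50.0, 90.0)


@dataclass(frozen=True)
class SubjectSpec:
    """Per-subject generative parameters."""

    group: str  # DLB-like or AD-like
    dominant_freq: float  # Hz
    freq_variability: float  # random-walk SD, Hz per sqrt(second)
    slow_power_gain: float
    age: float
    gender: str
    seed: int
    subject_id: str = ""


def _interp_params(lam: float) -> dict:
    """DLB-like parameter set at separation lam (equals AD-like at 0)."""
    out = {}
    for key in _AD_PARAMS:
        a, d = _AD_PARAMS[key], _DLB_PARAMS[key]
        if key == "freq_clip":
            out[key] = tuple(
                (1 - lam) * np.asarray(a) + lam * np.asarray(d)
            )
        else:
            out[key] = (1 - lam) * a + lam * d
    return out


def _truncated_normal(rng, mean, sd, lo, hi) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(x, lo, hi))


def draw_subject(
    spec: CohortSpec, group: str, rng: np.random.Generator, subject_id: str = ""
) -> SubjectSpec:
    """Draw one subject's generative parameters for the given group."""
    params = _AD_PARAMS if group == AD_LIKE else _interp_params(spec.separation)
    lo, hi = params["freq_clip"]
    f0 = _truncated_normal(rng, params["freq_mean"], params["freq_sd"], lo, hi)
    fv = max(0.05, rng.normal(params["variability_mean"], params["variability_sd"]))
    sg = max(0.1, rng.normal(params["slow_gain_mean"], params["slow_gain_sd"]))
    age = _truncated_normal(
        rng, spec.age_mean, spec.age_sd, spec.age_range[0], spec.age_range[1]
    )
    gender = "M" if rng.random() < 0.5 else "F"
    return SubjectSpec(
        group=group,
        dominant_freq=f0,
        freq_variability=fv,
        slow_power_gain=sg,
        age=age,
        gender=gender,
        seed=int(rng.integers(2**31)),
        subject_id=subject_id,
    )


def _pink_noise(rng, n: int, rms: float) -> np.ndarray:
    """1/f-power noise of the requested RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = np.inf  # kill DC
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x * (rms / x.std())


def _band_noise(rng, n: int, fs: float, band: tuple[float, float], rms: float):
    sos = _signal.butter(4, band, btype="bandpass", output="sos", fs=fs)
    x = _signal.sosfilt(sos, rng.standard_normal(n))
    return x * (rms / x.std())


def _reflected_walk(rng, n: int, fs: float, center: float, step_sd: float,
                    half_width: float) -> np.ndarray:
    """Random walk reflected into [center - hw, center + hw]."""
    inc = rng.normal(0.0, step_sd / np.sqrt(fs), n)
    w = center + np.cumsum(inc)
    lo, hi = center - half_width, center + half_width
    period = 2 * (hi - lo)
    z = np.mod(w - lo, period)
    return lo + np.where(z <= hi - lo, z, period - z)


def generate_subject_eeg(subject: SubjectSpec, spec: CohortSpec) -> EEGRecord:
    """Synthesize one subject's 19-channel recording (microvolts)."""
    if spec.duration < 150:
        raise ValueError("recordings shorter than 150 s are not analyzable")
    if spec.fs < 160:
        raise ValueError("sampling rate must be >= 160 Hz for the 70 Hz band edge")
    fs = spec.fs
    n = int(round(spec.duration * fs))
    rng = np.random.default_rng(subject.seed)

    # posterior dominant rhythm with wandering instantaneous frequency
    half_width = max(1.0, 2.5 * subject.freq_variability)
    inst_freq = _reflected_walk(
        rng, n, fs, subject.dominant_freq, subject.freq_variability, half_width
    )
    phase = 2 * np.pi * np.cumsum(inst_freq) / fs
    rhythm = RHYTHM_AMP_UV * np.sin(phase)

    slow = _band_noise(rng, n, fs, (1.0, 4.0), SLOW_RMS_UV * subject.slow_power_gain)
    shared = _pink_noise(rng, n, PINK_RMS_UV)

    data = np.empty((len(CANONICAL_CHANNELS), n))
    for c in range(data.shape[0]):
        data[c] = (
            _RHYTHM_GAIN[c] * rhythm
            + slow
            + SHARED_MIX * shared
            + _pink_noise(rng, n, PINK_RMS_UV)
        )

    if spec.artefact_rate > 0:
        _inject_artefacts(rng, data, fs, spec.artefact_rate)

    return EEGRecord(
        data=data,
        sampling_rate=fs,
        channel_labels=CANONICAL_CHANNELS,
        subject_id=subject.subject_id,
        subject_age=round(subject.age),
        subject_gender=subject.gender,
        meta={"group": subject.group, "dominant_freq": subject.dominant_freq},
    )


def _inject_artefacts(rng, data: np.ndarray, fs: float, rate: float) -> None:
    """Add blink transients (frontal) and EMG bursts (temporal) in place."""
    n = data.shape[1]
    minutes = n / fs / 60.0
    for kind in ("blink", "emg"):
        for _ in range(rng.poisson(rate * minutes)):
            if kind == "blink":
                width = int(0.4 * fs)
                t0 = rng.integers(0, n - width)
                pulse = 120.0 * np.hanning(width)
                data[:, t0 : t0 + width] += np.outer(_FRONTAL_GAIN, pulse)
            else:
                width = int(0.5 * fs)
                t0 = rng.integers(0, n - width)
                sos = _signal.butter(4, 20.0, btype="highpass", output="sos", fs=fs)
                burst = _signal.sosfilt(sos, rng.standard_normal(width))
                burst *= 60.0 / burst.std()
                burst *= np.hanning(width)
                data[:, t0 : t0 + width] += np.outer(_TEMPORAL_GAIN, burst)


def generate_cohort_records(
    spec: CohortSpec,
) -> tuple[list[EEGRecord], pd.DataFrame]:
    """All cohort recordings in memory, plus the manifest table.

    Subject ``i`` (DLB-like first, then AD-like) is generated from the
    child seed sequence ``(spec.seed, i)``, so any subject can be
    regenerated independently.
    """
    records = []
    rows = []
    groups = [DLB_LIKE] * spec.n_dlb + [AD_LIKE] * spec.n_ad
    for i, group in enumerate(groups):
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, i)))
        sid = f"S{i:03d}"
        subj = draw_subject(spec, group, rng, subject_id=sid)
        records.append(generate_subject_eeg(subj, spec))
        rows.append(
            {
                "subject_id": sid,
                "age": round(subj.age),
                "gender": subj.gender,
                "diagnosis": group,
                "drug": "",
                "dose_mg_per_day": "",
            }
        )
    return records, pd.DataFrame(rows)


def generate_cohort(spec: CohortSpec, out_dir) -> pd.DataFrame:
    """Write the cohort as EDF files plus manifest.csv and truth.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, manifest = generate_cohort_records(spec)
    paths = []
    for rec in records:
        write_edf(rec, out / f"{rec.subject_id}.edf")
        paths.append(f"{rec.subject_id}.edf")  # relative to the manifest
    manifest = manifest.copy()
    manifest.insert(1, "edf_path", paths)
    manifest.to_csv(out / "manifest.csv", index=False)
    manifest[["subject_id", "diagnosis"]].to_csv(out / "truth.csv", index=False)
    return manifest
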
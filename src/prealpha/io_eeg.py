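"""Reading, writing and referencing of 19-channel 10-20 EEG records.

The analysis montage is the classical 19-electrode International 10-20 set.
Records are kept in memory in microvolts, channels in a fixed canonical
order; every downstream channel index refers to this order:

    Fp1 Fp2 F3 F4 F7 F8 Fz T3 T4 T5 T6 C3 C4 Cz P3 P4 Pz O1 O2

EDF/EDF+ is the only supported on-disk format.  Reading goes through
:mod:`mne`; writing is a minimal 16-bit EDF writer (one-second data
records) sufficient for fixtures and simulated cohorts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import FormatError, IdempotencyWarning, MontageError

logger = logging.getLogger(__name__)

#: Canonical 10-20 channel order (old T3/T4/T5/T6 nomenclature).
CANONICAL_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz",
    "T3", "T4", "T5", "T6", "C3", "C4", "Cz",
    "P3", "P4", "Pz", "O1", "O2",
)

#: Modern (10-10) names accepted as synonyms for the older temporal labels.
CHANNEL_SYNONYMS: dict[str, str] = {
    "T7": "T3",
    "T8": "T4",
    "P7": "T5",
    "P8": "T6",
}

_CANONICAL_UPPER = {name.upper(): name for name in CANONICAL_CHANNELS}
_SYNONYM_UPPER = {k.upper(): v for k, v in CHANNEL_SYNONYMS.items()}

_NONEEG_MARKERS = ("EOG", "ECG", "EKG", "EMG", "ANNOTATION", "STATUS", "MARKER", "RESP")


def canonicalize_label(label: str) -> str | None:
    """Map a raw EDF channel label onto a canonical 10-20 name.

    Strips common ``"EEG "`` prefixes and reference suffixes (``-REF``,
    ``-LE`` ...), matches case-insensitively and resolves the modern
    T7/T8/P7/P8 names to T3/T4/T5/T6.  Returns ``None`` when the label is
    not one of the 19 montage electrodes.
    """
    s = label.strip()
    up = s.upper()
    if any(m in up for m in _NONEEG_MARKERS):
        return None
    if up.startswith("EEG"):
        up = up[3:].strip().lstrip(":").strip()
    up = up.split("-")[0].strip()
    if up in _CANONICAL_UPPER:
        return _CANONICAL_UPPER[up]
    if up in _SYNONYM_UPPER:
        return _SYNONYM_UPPER[up]
    return None


@dataclass
class EEGRecord:
    """A multichannel resting EEG recording in microvolts.

    ``data`` is shaped ``(n_channels, n_samples)``; after :meth:`validate`
    the rows follow :data:`CANONICAL_CHANNELS` exactly.
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...] = CANONICAL_CHANNELS
    reference: str = "as-recorded"  # {"as-recorded", "average"}
    subject_id: str = ""
    subject_age: float | None = None
    subject_gender: str | None = None  # {"M", "F"}
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.n_samples / self.sampling_rate

    def validate(self) -> "EEGRecord":
        """Check montage completeness and return a canonically ordered copy."""
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.n_channels != len(self.channel_labels):
            raise ValueError("label/data channel count mismatch")
        present = {lab: i for i, lab in enumerate(self.channel_labels)}
        missing = [c for c in CANONICAL_CHANNELS if c not in present]
        if missing:
            raise MontageError(missing)
        order = [present[c] for c in CANONICAL_CHANNELS]
        return replace(
            self,
            data=self.data[order],
            channel_labels=CANONICAL_CHANNELS,
        )


def apply_average_reference(record: EEGRecord) -> EEGRecord:
    """Re-reference every channel to the instantaneous mean of all 19.

    After application the mean across channels is zero at every sample.
    Idempotent: re-applying to an already average-referenced record warns
    and returns it unchanged.
    """
    if record.reference == "average":
        warnings.warn(
            "record is already average-referenced; no-op", IdempotencyWarning
        )
        return record
    rec = record.validate()
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return replace(rec, data=data, reference="average")


# ---------------------------------------------------------------------------
# EDF I/O


def _read_header_fields(path: Path) -> tuple[str, list[str], list[str]]:
    """Return (patient field, signal labels, transducer fields) from an EDF header."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        patient = head[8:88].decode("ascii", errors="replace").strip()
        ns = int(head[252:256].decode("ascii").strip() or 0)
        sig = fh.read(ns * 256)
    labels = [
        sig[16 * i : 16 * (i + 1)].decode("ascii", errors="replace").strip()
        for i in range(ns)
    ]
    off = 16 * ns
    transducers = [
        sig[off + 80 * i : off + 80 * (i + 1)]
        .decode("ascii", errors="replace")
        .strip()
        for i in range(ns)
    ]
    return patient, labels, transducers


def _parse_patient_field(patient: str) -> tuple[str, str | None, float | None]:
    """Parse ``"<id> <M|F> <age>"`` as written by :func:`write_edf`."""
    toks = patient.split()
    sid = toks[0] if toks else ""
    gender = None
    age = None
    for t in toks[1:]:
        if t.upper() in ("M", "F"):
            gender = t.upper()
        else:
            try:
                age = float(t)
            except ValueError:
                pass
    return sid, gender, age


def read_edf(path) -> EEGRecord:
    """Read an EDF/EDF+ file into a validated, canonically ordered record.

    Labels are mapped through the synonym table; non-EEG channels (EOG,
    ECG, annotations ...) are dropped with a log entry.  A missing montage
    electrode raises :class:`MontageError`; an unparseable file raises
    :class:`FormatError`.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except FormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - mne raises many types
        raise FormatError(f"{path}: not readable as EDF ({exc})") from exc

    keep_idx: list[int] = []
    keep_names: list[str] = []
    for i, name in enumerate(raw.ch_names):
        canon = canonicalize_label(name)
        if canon is None:
            logger.info("dropping non-EEG channel %r", name)
            continue
        keep_idx.append(i)
        keep_names.append(canon)
    missing = [c for c in CANONICAL_CHANNELS if c not in keep_names]
    if missing:
        raise MontageError(missing)

    data = raw.get_data(picks=keep_idx, units="uV")

    patient, _, transducers = _read_header_fields(path)
    sid, gender, age = _parse_patient_field(patient)
    if not any("imped" in t.lower() for t in transducers):
        logger.warning(
            "%s: no impedance annotation in transducer fields "
            "(the 10 kOhm rule cannot be checked post hoc)",
            path.name,
        )

    rec = EEGRecord(
        data=data,
        sampling_rate=float(raw.info["sfreq"]),
        channel_labels=tuple(keep_names),
        subject_id=sid,
        subject_age=age,
        subject_gender=gender,
    )
    return rec.validate()


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field too long: {s!r}")
    return s.ljust(width).encode("ascii")


def write_edf(record: EEGRecord, path) -> Path:
    """Write a validated record as a plain 16-bit EDF file.

    Uses one-second data records, so the recording must span a whole
    number of seconds with an integer number of samples per second.
    Subject id, gender and age are stored in the patient field.  Samples
    are quantized to the 16-bit digital range over a symmetric physical
    range, so a round trip reproduces them to well under 0.01 uV for
    ordinary EEG amplitudes.
    """
    rec = record.validate()
    if not np.all(np.isfinite(rec.data)):
        raise ValueError("record contains non-finite samples")
    spr = rec.sampling_rate
    if abs(spr - round(spr)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(spr))
    n_records, rem = divmod(rec.n_samples, spr)
    if rem:
        raise ValueError("EDF writer requires a whole number of seconds")

    path = Path(path)
    nch = rec.n_channels
    amp = np.abs(rec.data).max(axis=1)
    pmax = np.maximum(1.0, np.ceil(amp))  # uV, symmetric
    # symmetric digital range so zero maps to zero exactly
    dig_min, dig_max = -32767, 32767

    patient = " ".join(
        str(x)
        for x in (
            rec.subject_id or "X",
            rec.subject_gender or "X",
            "X" if rec.subject_age is None else f"{rec.subject_age:g}",
        )
    )
    header = b"".join(
        [
            _ascii("0", 8),
            _ascii(patient[:80], 80),
            _ascii("Startdate 01-JAN-2000", 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(256 * (1 + nch), 8),
            _ascii("", 44),
            _ascii(n_records, 8),
            _ascii(1, 8),
            _ascii(nch, 4),
        ]
    )
    sig = b"".join(_ascii(lab, 16) for lab in rec.channel_labels)
    sig += b"".join(_ascii("AgAgCl impedance<=10kOhm"[:80], 80) for _ in range(nch))
    sig += b"".join(_ascii("uV", 8) for _ in range(nch))
    sig += b"".join(_ascii(f"{-p:g}", 8) for p in pmax)
    sig += b"".join(_ascii(f"{p:g}", 8) for p in pmax)
    sig += b"".join(_ascii(dig_min, 8) for _ in range(nch))
    sig += b"".join(_ascii(dig_max, 8) for _ in range(nch))
    sig += b"".join(_ascii("BP 0.1-70Hz"[:80], 80) for _ in range(nch))
    sig += b"".join(_ascii(spr, 8) for _ in range(nch))
    sig += b"".join(_ascii("", 32) for _ in range(nch))

    scale = (dig_max - dig_min) / (2.0 * pmax)
    digital = np.rint((rec.data + pmax[:, None]) * scale[:, None]) + dig_min
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())
    return path
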
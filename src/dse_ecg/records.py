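"""Core record types for 12-lead ECG classification.

The unit of data is one patient record: a 12 x L voltage matrix in mV
sampled at 500 Hz, plus age, sex and (for labelled data) one of nine
rhythm classes — normal sinus rhythm and eight arrhythmias.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Fixed class order used everywhere (confusion matrices, softmax output,
#: manifests). Index 0 is normal rhythm, 1..8 the eight arrhythmias.
CLASSES: tuple[str, ...] = (
    "Normal", "AF", "I-AVB", "LBBB", "RBBB", "PAC", "PVC", "STD", "STE",
)

#: Standard 12-lead montage order; rows of ``EcgRecord.signal``.
LEAD_NAMES: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

N_LEADS = 12
DEFAULT_FS = 500.0

#: Sub-abnormal groupings: AF alone; conduction blocks; premature
#: contractions; ST-segment changes.
SUBABNORMAL_GROUPS: dict[str, tuple[str, ...]] = {
    "AF": ("AF",),
    "Block": ("I-AVB", "LBBB", "RBBB"),
    "PC": ("PAC", "PVC"),
    "ST": ("STD", "STE"),
}


class FormatError(ValueError):
    """Raised when an on-disk ECG artifact violates the expected format."""


@dataclass
class EcgRecord:
    """One 12-lead ECG record.

    Parameters
    ----------
    record_id : str
        Stable identifier (e.g. ``"A0001"``).
    signal : ndarray of shape (12, L)
        Voltages in mV, one row per lead in `LEAD_NAMES` order.
    fs : float
        Sampling rate in Hz.
    age : float or None
        Patient age in years; ``None`` when missing.
    sex : str or None
        ``"Female"`` / ``"Male"``; ``None`` when missing.
    label : str or None
        One of `CLASSES`; ``None`` for unlabeled inference input.
    secondary_labels : tuple of str
        Additional diagnoses carried for audit; unused by training.
    """

    record_id: str
    signal: np.ndarray
    fs: float = DEFAULT_FS
    age: float | None = None
    sex: str | None = None
    label: str | None = None
    secondary_labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2 or self.signal.shape[0] != N_LEADS:
            raise FormatError(
                f"expected 12 leads, got signal shape {self.signal.shape}"
            )
        if self.signal.shape[1] < 1:
            raise FormatError("signal must contain at least one sample")
        if not np.isfinite(self.signal).all():
            raise FormatError("signal contains non-finite values")
        if self.fs <= 0:
            raise FormatError(f"sampling rate must be positive, got {self.fs}")
        for lab in (self.label, *self.secondary_labels):
            if lab is not None and lab not in CLASSES:
                raise FormatError(
                    f"unknown label {lab!r}; permitted: {', '.join(CLASSES)}"
                )
        if self.sex is not None and self.sex not in ("Female", "Male"):
            raise FormatError(f"sex must be 'Female', 'Male' or None, got {self.sex!r}")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    def with_signal(self, signal: np.ndarray) -> "EcgRecord":
        """Copy of this record carrying a new voltage matrix."""
        return replace(self, signal=signal)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EcgRecord):
            return NotImplemented
        return (
            self.record_id == other.record_id
            and self.fs == other.fs
            and self.age == other.age
            and self.sex == other.sex
            and self.label == other.label
            and self.secondary_labels == other.secondary_labels
            and self.signal.shape == other.signal.shape
            and bool(np.array_equal(self.signal, other.signal))
        )


@dataclass
class LabelManifest:
    """Mapping record_id -> (first label, secondary labels).

    The first label is the training target; secondary labels are kept
    accessible but unused by the 9-class single-softmax model.
    """

    entries: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def add(self, record_id: str, labels: tuple[str, ...]) -> None:
        if record_id in self.entries:
            raise FormatError(f"duplicate record id {record_id!r} in manifest")
        if not labels:
            raise FormatError(f"record {record_id!r} has no label")
        for lab in labels:
            if lab not in CLASSES:
                raise FormatError(
                    f"unknown label {lab!r} for {record_id!r}; "
                    f"permitted: {', '.join(CLASSES)}"
                )
        self.entries[record_id] = tuple(labels)

    def first_label(self, record_id: str) -> str:
        return self.entries[record_id][0]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, record_id: str) -> bool:
        return record_id in self.entries
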
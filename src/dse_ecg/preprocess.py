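"""Signal conditioning and 2D ECG construction.

The pipeline turns a 12-lead record into fixed-size network inputs:

1. zero-phase Butterworth bandpass (0.5–49 Hz) per lead, removing baseline
   wander, 50 Hz power-line interference and high-frequency muscle noise;
2. splicing the leads into a 2D plane ``A ∈ R^{L×12}`` (columns = leads),
   treated like a grayscale image;
3. min–max normalization of the whole record into the symmetric interval
   [−3 mV, 3 mV]:  ``A_ij ← R_min + (R_max−R_min)(A_ij−A_min)/(A_max−A_min)``
   with A_min/A_max taken over all leads of the record jointly;
4. slicing into 8192-sample windows (16.384 s at 500 Hz) with 4096-sample
   overlap: records shorter than 8192 are zero-padded, records shorter than
   1.5×8192 are tail-truncated, longer records yield
   ``n = ⌊2L/8192⌋ − 1`` overlapping slices — the training-set augmentation;
5. dimension expansion to ``8192×12×1`` (a one-channel image).

`EcgPreprocessor` wraps the pipeline as a stateless sklearn-style
transformer; the module-level functions expose each stage.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .records import N_LEADS, EcgRecord

SLICE_LEN = 8192
OVERLAP = 4096
LONG_THRESHOLD_FACTOR = 1.5

WELCH_WINDOWS = {
    "blackman": "blackman",
    "hanning": "hann",
    "triangular": "triang",
}


class DegenerateRecordError(ValueError):
    """Raised for records that cannot be normalized (zero amplitude range)."""


@dataclass(frozen=True)
class FilterSpec:
    """Bandpass specification. Defaults: Butterworth order 3, 0.5–49 Hz,
    applied forward-backward (zero-phase) to avoid waveform distortion."""

    low_cut: float = 0.5
    high_cut: float = 49.0
    order: int = 3
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if not 0 < self.low_cut < self.high_cut:
            raise ValueError(
                f"need 0 < low_cut < high_cut, got ({self.low_cut}, {self.high_cut})"
            )
        if self.high_cut >= fs / 2:
            raise ValueError(
                f"high_cut {self.high_cut} Hz must lie below Nyquist ({fs / 2} Hz)"
            )
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


@dataclass(frozen=True)
class NormalizationParams:
    """Audit trail of one min–max normalization: target interval
    [r_min, r_max] (mV) and the observed record extrema [a_min, a_max]."""

    r_min: float
    r_max: float
    a_min: float
    a_max: float


@dataclass(frozen=True)
class SlicingPolicy:
    slice_len: int = SLICE_LEN
    overlap: int = OVERLAP
    long_threshold_factor: float = LONG_THRESHOLD_FACTOR

    def __post_init__(self) -> None:
        if not 0 < self.overlap < self.slice_len:
            raise ValueError(
                f"need 0 < overlap < slice_len, got {self.overlap}, {self.slice_len}"
            )


@dataclass
class TwoDimSlice:
    """One normalized 2D ECG slice (slice_len × 12 × 1) with provenance."""

    values: np.ndarray
    record_id: str
    slice_index: int
    origin_offset: int
    age: float | None = None
    sex: str | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[1:] != (N_LEADS, 1):
            raise ValueError(
                f"slice values must be (slice_len, 12, 1), got {self.values.shape}"
            )


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def design_bandpass(spec: FilterSpec, fs: float) -> np.ndarray:
    """Second-order sections of the Butterworth bandpass for `fs`."""
    spec.validate(fs)
    return sps.butter(
        spec.order, [spec.low_cut, spec.high_cut], btype="bandpass", fs=fs,
        output="sos",
    )


def bandpass(record: EcgRecord, spec: FilterSpec = FilterSpec()) -> EcgRecord:
    """Bandpass-filter every lead independently; length is preserved."""
    sos = design_bandpass(spec, record.fs)
    if spec.zero_phase:
        padlen = min(record.n_samples - 1, 3 * (2 * sos.shape[0] + 1) * 10)
        filtered = sps.sosfiltfilt(sos, record.signal, axis=1, padlen=padlen)
    else:
        filtered = sps.sosfilt(sos, record.signal, axis=1)
    return record.with_signal(filtered)


def bandpass_response(spec: FilterSpec, fs: float, freqs) -> np.ndarray:
    """Magnitude response of the realized filter at `freqs` (Hz).

    Zero-phase application squares the single-pass magnitude.
    """
    sos = design_bandpass(spec, fs)
    _, h = sps.sosfreqz(sos, worN=np.atleast_1d(freqs), fs=fs)
    mag = np.abs(h)
    return mag**2 if spec.zero_phase else mag


def welch_psd(
    lead: np.ndarray,
    fs: float = 500.0,
    window: str = "hanning",
    nperseg: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch power spectral density of a single lead.

    `window` is one of {"blackman", "hanning", "triangular"}; `nperseg`
    is typically 256, 512 or 1024. Used as the denoising diagnostic: after
    bandpass filtering the density above the 49 Hz cutoff collapses.
    """
    if window not in WELCH_WINDOWS:
        raise ValueError(
            f"unknown window {window!r}; supported: "
            + ", ".join(sorted(WELCH_WINDOWS))
        )
    lead = np.asarray(lead, dtype=np.float64)
    if lead.size < nperseg:
        raise ValueError(f"series length {lead.size} < nperseg {nperseg}")
    return sps.welch(lead, fs=fs, window=WELCH_WINDOWS[window], nperseg=nperseg)


def minmax_normalize(
    A: np.ndarray, r_min: float = -3.0, r_max: float = 3.0
) -> tuple[np.ndarray, NormalizationParams]:
    """Affinely rescale a 2D ECG so its extrema hit exactly [r_min, r_max] mV.

    The observed minimum/maximum are taken over the entire matrix (all leads
    of the record jointly). Constant records have zero amplitude range and
    are rejected.
    """
    A = np.asarray(A, dtype=np.float64)
    if not np.isfinite(A).all():
        raise ValueError("2D ECG contains non-finite values")
    a_min, a_max = float(A.min()), float(A.max())
    if a_max == a_min:
        raise DegenerateRecordError(
            "zero amplitude range: record is constant and cannot be normalized"
        )
    out = r_min + (r_max - r_min) * (A - a_min) / (a_max - a_min)
    # the affine map can overshoot by one ulp; the extrema themselves map
    # to the endpoints exactly, so clipping only removes rounding spill
    np.clip(out, r_min, r_max, out=out)
    return out, NormalizationParams(r_min=r_min, r_max=r_max, a_min=a_min, a_max=a_max)


def to_two_dimensional(record: EcgRecord) -> np.ndarray:
    """Splice the 12 leads into the L×12 plane (column j = lead j)."""
    return record.signal.T.copy()


def slice_two_dim(
    A: np.ndarray, policy: SlicingPolicy = SlicingPolicy()
) -> list[tuple[np.ndarray, int]]:
    """Cut an L×12 plane into fixed-length windows; returns (window, offset).

    Branches:
      L < slice_len                      → one window, zero-padded at the tail;
      slice_len ≤ L < 1.5·slice_len      → one window, tail truncated;
      L ≥ 1.5·slice_len                  → n = ⌊2L/slice_len⌋ − 1 windows,
                                           consecutive starts `overlap` apart.
    """
    A = np.asarray(A, dtype=np.float64)
    L = A.shape[0]
    if L == 0:
        raise ValueError("cannot slice an empty record")
    S = policy.slice_len
    if L < S:
        padded = np.zeros((S, A.shape[1]), dtype=A.dtype)
        padded[:L] = A
        return [(padded, 0)]
    if L < policy.long_threshold_factor * S:
        return [(A[:S].copy(), 0)]
    n = int(2 * L // S) - 1
    return [(A[i * policy.overlap : i * policy.overlap + S].copy(), i * policy.overlap)
            for i in range(n)]


def expand_dims(window: np.ndarray) -> np.ndarray:
    """Add the trailing one-channel axis: (T, 12) → (T, 12, 1)."""
    window = np.asarray(window)
    if window.ndim != 2:
        raise ValueError(
            f"expected a 2-axis slice, got {window.ndim} axes "
            "(already expanded?)"
        )
    return window[:, :, np.newaxis]


def preprocess_record(
    record: EcgRecord,
    filter_spec: FilterSpec = FilterSpec(),
    policy: SlicingPolicy = SlicingPolicy(),
    r_min: float = -3.0,
    r_max: float = 3.0,
) -> list[TwoDimSlice]:
    """Full pipeline: filter → 2D → normalize → slice → expand.

    Normalization is computed once per record, so all its slices share one
    affine map; zero-padding happens after normalization, hence padded
    samples are exactly 0.
    """
    filtered = bandpass(record, filter_spec)
    plane = to_two_dimensional(filtered)
    normalized, _params = minmax_normalize(plane, r_min=r_min, r_max=r_max)
    slices = []
    for idx, (window, offset) in enumerate(slice_two_dim(normalized, policy)):
        slices.append(
            TwoDimSlice(
                values=expand_dims(window),
                record_id=record.record_id,
                slice_index=idx,
                origin_offset=offset,
                age=record.age,
                sex=record.sex,
                label=record.label,
            )
        )
    return slices


def welch_diagnostic_plot(
    record: EcgRecord,
    path,
    lead: int = 0,
    filter_spec: FilterSpec = FilterSpec(),
    npersegs: tuple[int, ...] = (256, 512, 1024),
    windows: tuple[str, ...] = ("blackman", "hanning", "triangular"),
) -> None:
    """Export the denoising diagnostic: Welch PSD of one lead before (top
    row) and after (bottom row) bandpass filtering, one column per segment
    length, all three windows overlaid per panel."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    filtered = bandpass(record, filter_spec)
    fig, axes = plt.subplots(2, len(npersegs), figsize=(4 * len(npersegs), 6),
                             sharex=True)
    for col, nperseg in enumerate(npersegs):
        for row, rec in enumerate((record, filtered)):
            ax = axes[row, col]
            for window in windows:
                f, p = welch_psd(rec.signal[lead], fs=rec.fs,
                                 window=window, nperseg=nperseg)
                ax.semilogy(f, p, label=window, linewidth=0.8)
            ax.set_title(f"{'raw' if row == 0 else 'filtered'}, nperseg={nperseg}")
            ax.set_xlabel("frequency (Hz)")
            if col == 0:
                ax.set_ylabel("PSD (mV$^2$/Hz)")
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


class EcgPreprocessor(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: list of `EcgRecord` → list of `TwoDimSlice`.

    Stateless (fit is a no-op); parameters mirror `FilterSpec`,
    `SlicingPolicy` and the normalization target interval.
    """

    def __init__(
        self,
        low_cut: float = 0.5,
        high_cut: float = 49.0,
        order: int = 3,
        zero_phase: bool = True,
        slice_len: int = SLICE_LEN,
        overlap: int = OVERLAP,
        r_min: float = -3.0,
        r_max: float = 3.0,
    ):
        self.low_cut = low_cut
        self.high_cut = high_cut
        self.order = order
        self.zero_phase = zero_phase
        self.slice_len = slice_len
        self.overlap = overlap
        self.r_min = r_min
        self.r_max = r_max

    def _filter_spec(self) -> FilterSpec:
        return FilterSpec(
            low_cut=self.low_cut, high_cut=self.high_cut,
            order=self.order, zero_phase=self.zero_phase,
        )

    def _policy(self) -> SlicingPolicy:
        return SlicingPolicy(slice_len=self.slice_len, overlap=self.overlap)

    def fit(self, X, y=None):  # noqa: D102 - stateless
        self.n_features_in_ = len(X)
        return self

    def transform(self, X: list[EcgRecord]) -> list[TwoDimSlice]:
        out: list[TwoDimSlice] = []
        for record in X:
            out.extend(
                preprocess_record(
                    record,
                    filter_spec=self._filter_spec(),
                    policy=self._policy(),
                    r_min=self.r_min,
                    r_max=self.r_max,
                )
            )
        return out
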
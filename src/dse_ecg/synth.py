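"""Synthetic 12-lead ECG generator.

Produces labelled records with the statistical structure the classifier
relies on, so the whole pipeline is exercisable without a clinical dataset:
500 Hz 12-lead traces of variable length (lognormal durations, mean ≈16 s,
clipped to 6–60 s, ~13% of records longer than 1.5× the 16.384 s slice
length), P-QRS-T morphology built from five Gaussian bumps with a fixed
per-lead polarity/scale table, class-conditioned abnormalities, and additive
baseline-wander / 50 Hz power-line / broadband noise plus age/sex covariates.

Class rules:

* ``Normal`` — regular RR, standard morphology;
* ``AF`` — i.i.d. jittered RR intervals (cv ≥ 0.15), absent P waves;
* ``I-AVB`` — PR interval prolonged beyond 200 ms;
* ``LBBB`` / ``RBBB`` — QRS widened beyond 120 ms with lead-dependent
  polarity changes (LBBB concentrated in I, V1, V2, V5, V6, aVR; RBBB in
  V1–V3 with deep lateral S waves);
* ``PAC`` / ``PVC`` — at least one premature beat (the PVC ectopic beat has
  a widened, high-amplitude QRS and inverted T);
* ``STD`` / ``STE`` — ST-segment offset of ∓/±0.1–0.3 mV.

The morphology is an analytic Gaussian-bump model, not a dynamical ECG
simulator: every feature the classes manipulate is directly controlled,
which is what the tests need; it does not attempt physiological realism
beyond that.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal as sps

from .records import CLASSES, DEFAULT_FS, LEAD_NAMES, EcgRecord, LabelManifest

# Per-lead scale/polarity for the five waves (columns P, Q, R, S, T), rows in
# LEAD_NAMES order. Values follow standard lead geometry (aVR inverted,
# anterior leads with dominant S in V1/V2, tall R in II/V4); arbitrary but
# fixed — the class rules are defined relative to this table.
LEAD_WAVE_SCALE = np.array(
    [
        # P      Q      R      S      T
        [0.80, 0.80, 0.70, 0.50, 0.80],   # I
        [1.00, 1.00, 1.00, 1.00, 1.00],   # II
        [0.40, 0.50, 0.40, 0.80, 0.40],   # III
        [-0.80, 0.50, -0.90, -0.80, -0.80],  # aVR
        [0.30, 0.40, 0.30, 0.40, 0.30],   # aVL
        [0.70, 0.80, 0.70, 0.90, 0.70],   # aVF
        [0.30, 0.20, 0.25, 1.60, -0.40],  # V1
        [0.40, 0.30, 0.45, 1.80, 0.90],   # V2
        [0.50, 0.40, 0.70, 1.40, 1.10],   # V3
        [0.60, 0.60, 1.10, 1.00, 1.00],   # V4
        [0.70, 0.80, 1.05, 0.70, 0.90],   # V5
        [0.80, 0.90, 0.95, 0.50, 0.80],   # V6
    ]
)

_LEAD_INDEX = {name: i for i, name in enumerate(LEAD_NAMES)}

# Default class mix mirrors the CPSC2018 training-set profile (9 classes,
# strongly imbalanced: RBBB and AF dominate, LBBB and STE are rare).
CPSC_CLASS_COUNTS = {
    "Normal": 918, "AF": 1098, "I-AVB": 704, "LBBB": 207, "RBBB": 1695,
    "PAC": 574, "PVC": 653, "STD": 826, "STE": 202,
}
_total = sum(CPSC_CLASS_COUNTS.values())
DEFAULT_CLASS_MIX = {k: v / _total for k, v in CPSC_CLASS_COUNTS.items()}

# Lognormal duration parameters chosen so the mean is 16 s and the mass
# above 1.5 x 16.384 s is ~12.7% before clipping to [6, 60] s.
_DUR_MU = 2.6595
_DUR_SIGMA = 0.4756


@dataclass(frozen=True)
class BeatParams:
    """One cardiac cycle as five Gaussian bumps (P, Q, R, S, T).

    Amplitudes are lead-II values in mV; offsets are peak times relative to
    the R peak in seconds; widths are Gaussian sigmas in seconds. The
    rendered waveform for lead ℓ scales each bump by LEAD_WAVE_SCALE[ℓ].
    """

    amplitudes: tuple[float, ...] = (0.15, -0.10, 1.20, -0.25, 0.35)
    offsets: tuple[float, ...] = (-0.17, -0.040, 0.0, 0.040, 0.30)
    widths: tuple[float, ...] = (0.025, 0.010, 0.012, 0.012, 0.060)
    st_offset: float = 0.0              # mV, plateau between S and T
    lead_qrs_gain: tuple[float, ...] = (1.0,) * 12  # per-lead Q/R/S multiplier


NORMAL_BEAT = BeatParams()


@dataclass(frozen=True)
class SynthConfig:
    n_records: int = 100
    class_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX)
    )
    duration_range: tuple[float, float] = (6.0, 60.0)
    duration_lognorm: tuple[float, float] = (_DUR_MU, _DUR_SIGMA)
    fs: float = DEFAULT_FS
    heart_rate_range: tuple[float, float] = (55.0, 100.0)
    baseline_wander_amp: float = 0.10   # mV
    baseline_wander_freq: float = 0.30  # Hz
    line_noise_amp: float = 0.05        # mV at 50 Hz
    white_noise_sd: float = 0.03        # mV
    missing_rate: float = 0.02          # P(age or sex missing)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"class mix must sum to 1, sums to {total}")
        for cls in self.class_mix:
            if cls not in CLASSES:
                raise ValueError(f"unknown class {cls!r} in mix")
        if self.duration_range[0] <= 0:
            raise ValueError("durations must be positive")

    def noise_free(self) -> "SynthConfig":
        """Copy with all additive noise switched off."""
        return replace(
            self, baseline_wander_amp=0.0, line_noise_amp=0.0, white_noise_sd=0.0
        )


def synth_beat_template(
    lead_index: int,
    params: BeatParams = NORMAL_BEAT,
    fs: float = DEFAULT_FS,
    window: tuple[float, float] = (-0.35, 0.55),
) -> np.ndarray:
    """Render one cardiac cycle for a single lead on a window around R.

    Deterministic given `params`; the five bumps produce the P-QRS-T shape
    with the QRS complex dominating.
    """
    t = np.arange(window[0], window[1], 1.0 / fs)
    out = np.zeros_like(t)
    scale = LEAD_WAVE_SCALE[lead_index]
    for w, (amp, off, sd) in enumerate(
        zip(params.amplitudes, params.offsets, params.widths)
    ):
        gain = params.lead_qrs_gain[lead_index] if w in (1, 2, 3) else 1.0
        out += gain * scale[w] * amp * np.exp(-((t - off) ** 2) / (2 * sd**2))
    if params.st_offset:
        out += abs(scale[4]) * params.st_offset * _plateau(t, 0.06, 0.24)
    return out


def _plateau(t: np.ndarray, start: float, stop: float, edge: float = 0.02) -> np.ndarray:
    """Smooth unit plateau on [start, stop] (sigmoid edges of width `edge`)."""
    return 1.0 / (1.0 + np.exp(-(t - start) / edge)) - 1.0 / (
        1.0 + np.exp(-(t - stop) / edge)
    )


def _class_beat(label: str, rng: np.random.Generator) -> BeatParams:
    """Beat morphology for a class (timing abnormalities handled separately)."""
    if label == "AF":
        amps = (0.0, -0.10, 1.20, -0.25, 0.35)  # absent P
        return replace(NORMAL_BEAT, amplitudes=amps)
    if label == "I-AVB":
        # PR prolonged: P peak 0.28 s before R (interval > 200 ms)
        return replace(NORMAL_BEAT, offsets=(-0.28, -0.040, 0.0, 0.040, 0.30))
    if label in ("LBBB", "RBBB"):
        wide = replace(
            NORMAL_BEAT,
            offsets=(-0.20, -0.090, 0.0, 0.090, 0.34),
            widths=(0.025, 0.030, 0.035, 0.030, 0.060),
        )
        gain = np.ones(12)
        if label == "LBBB":
            for name in ("I", "V5", "V6"):
                gain[_LEAD_INDEX[name]] = 1.6      # broad lateral R
            for name in ("V1", "V2", "aVR"):
                gain[_LEAD_INDEX[name]] = -1.4     # deep anterior negativity
        else:  # RBBB
            for name in ("V1", "V2", "V3"):
                gain[_LEAD_INDEX[name]] = 1.8      # tall wide anterior R'
            for name in ("I", "V6"):
                gain[_LEAD_INDEX[name]] = 0.7
        return replace(wide, lead_qrs_gain=tuple(gain))
    if label == "STD":
        return replace(NORMAL_BEAT, st_offset=-float(rng.uniform(0.1, 0.3)))
    if label == "STE":
        return replace(NORMAL_BEAT, st_offset=float(rng.uniform(0.1, 0.3)))
    # Normal, PAC, PVC share the baseline morphology for on-grid beats
    return NORMAL_BEAT


_PVC_BEAT = BeatParams(
    amplitudes=(0.0, -0.18, 1.95, -0.45, -0.40),   # no P, tall QRS, inverted T
    offsets=(-0.17, -0.085, 0.0, 0.085, 0.36),
    widths=(0.025, 0.028, 0.032, 0.028, 0.070),
)


def _render_beat(
    signal: np.ndarray, t_r: float, params: BeatParams, fs: float
) -> None:
    """Add one beat (all 12 leads) to `signal` in place, centred at `t_r` s."""
    L = signal.shape[1]
    lo = max(0, int((t_r - 0.45) * fs))
    hi = min(L, int((t_r + 0.65) * fs) + 1)
    if hi <= lo:
        return
    t = np.arange(lo, hi) / fs - t_r
    gain = np.asarray(params.lead_qrs_gain)
    for w, (amp, off, sd) in enumerate(
        zip(params.amplitudes, params.offsets, params.widths)
    ):
        if amp == 0.0:
            continue
        bump = amp * np.exp(-((t - off) ** 2) / (2 * sd**2))
        lead_scale = LEAD_WAVE_SCALE[:, w] * (gain if w in (1, 2, 3) else 1.0)
        signal[:, lo:hi] += lead_scale[:, None] * bump[None, :]
    if params.st_offset:
        plateau = params.st_offset * _plateau(t, 0.06, 0.24)
        signal[:, lo:hi] += np.abs(LEAD_WAVE_SCALE[:, 4])[:, None] * plateau[None, :]


def synth_record(
    label: str,
    config: SynthConfig = SynthConfig(),
    rng: np.random.Generator | None = None,
    record_id: str = "S0000",
    duration: float | None = None,
) -> EcgRecord:
    """Generate one labelled 12-lead record under the class rules."""
    if label not in CLASSES:
        raise ValueError(f"unknown class {label!r}; permitted: {', '.join(CLASSES)}")
    rng = rng or np.random.default_rng(config.seed)
    fs = config.fs
    if duration is None:
        duration = _draw_duration(config, rng)
    L = int(round(duration * fs))
    hr = rng.uniform(*config.heart_rate_range)
    rr_mean = 60.0 / hr

    n_beats = int(duration / rr_mean) + 3
    if label == "AF":
        rr = rr_mean * np.clip(1.0 + 0.25 * rng.standard_normal(n_beats), 0.5, 1.9)
    else:
        rr = np.full(n_beats, rr_mean)
    r_times = 0.4 + np.cumsum(np.concatenate([[0.0], rr[:-1]]))

    base = _class_beat(label, rng)
    beats: list[tuple[float, BeatParams]] = [(t, base) for t in r_times if t < duration + 0.4]

    if label in ("PAC", "PVC") and len(beats) >= 3:
        # make every ~8th beat premature (at least one)
        ectopic = _PVC_BEAT if label == "PVC" else base
        idx = list(range(2, len(beats), 8)) or [1]
        for i in idx:
            t_prem = beats[i][0] - 0.32 * rr_mean
            beats[i] = (t_prem, ectopic)

    signal = np.zeros((12, L))
    for t_r, params in beats:
        _render_beat(signal, t_r, params, fs)

    t = np.arange(L) / fs
    if config.baseline_wander_amp > 0:
        phases = rng.uniform(0, 2 * np.pi, 12)
        amps = config.baseline_wander_amp * rng.uniform(0.5, 1.0, 12)
        signal += amps[:, None] * np.sin(
            2 * np.pi * config.baseline_wander_freq * t[None, :] + phases[:, None]
        )
    if config.line_noise_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        signal += config.line_noise_amp * np.sin(2 * np.pi * 50.0 * t + phase)[None, :]
    if config.white_noise_sd > 0:
        signal += config.white_noise_sd * rng.standard_normal(signal.shape)

    age = float(np.clip(np.round(rng.normal(60, 16)), 18, 92))
    sex = "Female" if rng.random() < 0.5 else "Male"
    if rng.random() < config.missing_rate:
        age = None
    if rng.random() < config.missing_rate:
        sex = None
    return EcgRecord(
        record_id=record_id, signal=signal, fs=fs, age=age, sex=sex, label=label
    )


def _draw_duration(config: SynthConfig, rng: np.random.Generator) -> float:
    mu, sigma = config.duration_lognorm
    d = float(np.exp(rng.normal(mu, sigma)))
    return float(np.clip(d, *config.duration_range))


def _class_counts(config: SynthConfig) -> dict[str, int]:
    """Largest-remainder apportionment of n_records over the mix."""
    mix = [(cls, config.class_mix.get(cls, 0.0)) for cls in CLASSES]
    raw = {cls: p * config.n_records for cls, p in mix}
    counts = {cls: int(np.floor(v)) for cls, v in raw.items()}
    short = config.n_records - sum(counts.values())
    remainders = sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)
    for cls in remainders[:short]:
        counts[cls] += 1
    return {cls: n for cls, n in counts.items() if n > 0}


def synth_dataset(
    config: SynthConfig = SynthConfig(),
) -> tuple[list[EcgRecord], LabelManifest]:
    """Generate a full labelled dataset plus its manifest.

    Same config (including seed) → bit-identical dataset. Class counts match
    the requested mix to within largest-remainder rounding (±1).
    """
    rng = np.random.default_rng(config.seed)
    labels: list[str] = []
    for cls, n in _class_counts(config).items():
        labels.extend([cls] * n)
    rng.shuffle(labels)
    records = []
    manifest = LabelManifest()
    for i, label in enumerate(labels):
        rec = synth_record(label, config, rng, record_id=f"S{i + 1:04d}")
        records.append(rec)
        manifest.add(rec.record_id, (label,))
    return records, manifest


# ---------------------------------------------------------------------------
# Simple waveform measurements (sanity instrumentation for the generator)
# ---------------------------------------------------------------------------

def detect_r_peaks(record: EcgRecord, lead: str = "II") -> np.ndarray:
    """R-peak sample indices via thresholded peak search on one lead."""
    x = record.signal[_LEAD_INDEX[lead]]
    height = 0.5 * np.max(np.abs(x))
    peaks, _ = sps.find_peaks(x, height=height, distance=int(0.25 * record.fs))
    return peaks


def measure_features(record: EcgRecord) -> dict[str, float]:
    """RR variability, QRS width, ST offset and P amplitude of a record.

    Intended for noise-free generated records; a crude but independent check
    that the class rules actually imprint their features on the waveform.
    """
    fs = record.fs
    lead2 = record.signal[_LEAD_INDEX["II"]]
    peaks = detect_r_peaks(record)
    out = {"n_beats": float(len(peaks))}
    if len(peaks) >= 3:
        rr = np.diff(peaks) / fs
        out["rr_mean"] = float(rr.mean())
        out["rr_cv"] = float(rr.std() / rr.mean())
        out["heart_rate"] = 60.0 / out["rr_mean"]
    qrs_widths, st_vals, p_amps = [], [], []
    for p in peaks:
        lo, hi = p - int(0.15 * fs), p + int(0.15 * fs)
        if lo < 0 or hi >= len(lead2):
            continue
        seg = np.abs(lead2[lo:hi])
        above = seg > 0.12
        i = p - lo
        a, b = i, i
        while a > 0 and above[a - 1]:
            a -= 1
        while b < len(above) - 1 and above[b + 1]:
            b += 1
        qrs_widths.append((b - a + 1) / fs)
        st_lo, st_hi = p + int(0.08 * fs), p + int(0.16 * fs)
        if st_hi < len(lead2):
            st_vals.append(np.mean(lead2[st_lo:st_hi]))
        p_lo, p_hi = p - int(0.22 * fs), p - int(0.10 * fs)
        if p_lo >= 0:
            p_amps.append(np.max(lead2[p_lo:p_hi]))
    if qrs_widths:
        out["qrs_width"] = float(np.median(qrs_widths))
    if st_vals:
        out["st_offset"] = float(np.median(st_vals))
    if p_amps:
        out["p_amplitude"] = float(np.median(p_amps))
    return out
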
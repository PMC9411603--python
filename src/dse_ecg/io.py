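"""Readers and writers for 12-lead ECG records.

Supported formats:

* CPSC2018-style MATLAB v5 ``.mat`` files — a struct ``ECG`` with fields
  ``data`` (12 x L, mV), ``age`` and ``sex``;
* a CSV label manifest (``Recording,First_label,Second_label,Third_label``);
* a lossless internal ``.npz`` archive used for intermediate artifacts;
* a minimal WFDB header+signal pair (MIT format 16, mV-scaled output).

Readers never reorder or truncate leads; files that declare a non-standard
lead order are remapped to `records.LEAD_NAMES` at read time.
"""
from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import scipy.io as sio

from .records import (
    DEFAULT_FS,
    LEAD_NAMES,
    N_LEADS,
    EcgRecord,
    FormatError,
    LabelManifest,
)

ARCHIVE_VERSION = 1


# ---------------------------------------------------------------------------
# CPSC2018 .mat dialect
# ---------------------------------------------------------------------------

def _scalar_or_none(value) -> float | None:
    arr = np.asarray(value)
    if arr.size == 0:
        return None
    v = arr.ravel()[0]
    try:
        f = float(v)
    except (TypeError, ValueError):
        return None
    return None if np.isnan(f) else f


def _sex_or_none(value) -> str | None:
    arr = np.asarray(value)
    if arr.size == 0:
        return None
    token = str(arr.ravel()[0]).strip()
    if not token:
        return None
    t = token.lower()
    if t in ("female", "f"):
        return "Female"
    if t in ("male", "m"):
        return "Male"
    return None


def read_cpsc_mat(path: str | Path, record_id: str | None = None) -> EcgRecord:
    """Read one CPSC2018-dialect ``.mat`` file into an `EcgRecord`.

    The file must hold a struct ``ECG`` with a 12 x L numeric ``data`` array
    (mV) plus ``age`` and ``sex`` entries; empty age/sex map to the missing
    sentinel ``None``. Sampling rate is 500 Hz unless the struct carries an
    ``fs`` field. The label is not stored in the .mat file; it comes from the
    manifest.
    """
    path = Path(path)
    try:
        mat = sio.loadmat(path, squeeze_me=False, struct_as_record=True)
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise FormatError(f"cannot parse {path} as MATLAB v5: {exc}") from exc
    if "ECG" not in mat:
        raise FormatError(f"{path}: missing struct 'ECG'")
    ecg = mat["ECG"]
    try:
        fields = ecg.dtype.names or ()
    except AttributeError:
        raise FormatError(f"{path}: 'ECG' is not a struct") from None
    if "data" not in fields:
        raise FormatError(f"{path}: struct 'ECG' lacks field 'data'")
    cell = ecg[0, 0]
    data = np.asarray(cell["data"], dtype=np.float64)
    data = np.atleast_2d(np.squeeze(data))
    if data.ndim != 2:
        raise FormatError(f"{path}: field 'data' is not a 2-D array")
    if data.shape[0] != N_LEADS:
        if data.shape[1] == N_LEADS:  # stored transposed
            data = data.T
        else:
            raise FormatError(
                f"{path}: expected 12 leads in field 'data', got shape {data.shape}"
            )
    if not np.issubdtype(data.dtype, np.number):
        raise FormatError(f"{path}: field 'data' is non-numeric")
    age = _scalar_or_none(cell["age"]) if "age" in fields else None
    sex = _sex_or_none(cell["sex"]) if "sex" in fields else None
    fs = _scalar_or_none(cell["fs"]) if "fs" in fields else None
    return EcgRecord(
        record_id=record_id or path.stem,
        signal=data,
        fs=float(fs) if fs else DEFAULT_FS,
        age=age,
        sex=sex,
    )


def write_cpsc_mat(record: EcgRecord, path: str | Path) -> None:
    """Write a record as a CPSC2018-dialect ``.mat`` file (label excluded)."""
    payload = {
        "data": record.signal,
        "age": np.array([[record.age]]) if record.age is not None else np.array([[]]),
        "sex": np.array([record.sex]) if record.sex is not None else np.array([""]),
    }
    if record.fs != DEFAULT_FS:
        payload["fs"] = np.array([[record.fs]])
    sio.savemat(Path(path), {"ECG": payload})


# ---------------------------------------------------------------------------
# Label manifest (REFERENCE.csv dialect)
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> LabelManifest:
    """Read a ``Recording,First_label,...`` CSV manifest.

    Rows carrying several labels retain all of them in printed order.
    Duplicate record ids and unknown label tokens raise `FormatError`.
    """
    manifest = LabelManifest()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise FormatError(f"{path}: empty manifest")
        for row in reader:
            if not row or not row[0].strip():
                continue
            record_id = row[0].strip()
            labels = tuple(tok.strip() for tok in row[1:] if tok.strip())
            manifest.add(record_id, labels)
    return manifest


def write_manifest(manifest: LabelManifest, path: str | Path) -> None:
    width = max((len(v) for v in manifest.entries.values()), default=1)
    names = ["First_label", "Second_label", "Third_label"]
    while len(names) < width:
        names.append(f"Label_{len(names) + 1}")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["Recording", *names[:width]])
        for record_id, labels in manifest.entries.items():
            writer.writerow([record_id, *labels, *[""] * (width - len(labels))])


# ---------------------------------------------------------------------------
# Internal archive (lossless round-trip)
# ---------------------------------------------------------------------------

def write_record(record: EcgRecord, path: str | Path) -> None:
    """Lossless archive of a record; the voltage matrix is stored bit-exact."""
    np.savez(
        Path(path),
        version=np.int64(ARCHIVE_VERSION),
        record_id=np.str_(record.record_id),
        signal=record.signal,
        fs=np.float64(record.fs),
        age=np.float64(np.nan if record.age is None else record.age),
        sex=np.str_(record.sex or ""),
        label=np.str_(record.label or ""),
        secondary_labels=np.array(record.secondary_labels, dtype="U16"),
    )


def read_record(path: str | Path) -> EcgRecord:
    with np.load(Path(path), allow_pickle=False) as z:
        version = int(z["version"])
        if version != ARCHIVE_VERSION:
            raise FormatError(
                f"{path}: archive version {version} unsupported "
                f"(expected {ARCHIVE_VERSION})"
            )
        age = float(z["age"])
        return EcgRecord(
            record_id=str(z["record_id"]),
            signal=z["signal"],
            fs=float(z["fs"]),
            age=None if np.isnan(age) else age,
            sex=str(z["sex"]) or None,
            label=str(z["label"]) or None,
            secondary_labels=tuple(z["secondary_labels"].tolist()),
        )


# ---------------------------------------------------------------------------
# Minimal WFDB (MIT format 16) support
# ---------------------------------------------------------------------------

def read_wfdb(header_path: str | Path) -> EcgRecord:
    """Read a WFDB header+signal pair (format 16 only), output in mV.

    Supports the single-``.dat``, 12-signal layout. Values are scaled by the
    per-signal gain (ADC units per mV) and baseline from the header.
    """
    header_path = Path(header_path)
    lines = [
        ln.strip()
        for ln in header_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    name, n_sig = head[0], int(head[1])
    fs = float(head[2]) if len(head) > 2 else DEFAULT_FS
    n_samp = int(head[3]) if len(head) > 3 else None
    if n_sig != N_LEADS:
        raise FormatError(f"{header_path}: expected 12 signals, got {n_sig}")
    dat_names, gains, baselines, lead_labels = [], [], [], []
    for spec in lines[1 : 1 + n_sig]:
        parts = spec.split()
        dat_names.append(parts[0])
        if not parts[1].startswith("16"):
            raise FormatError(
                f"{header_path}: only WFDB format 16 is supported, got {parts[1]}"
            )
        gain_field = parts[2] if len(parts) > 2 else "200"
        gain_tok = gain_field.split("/")[0]
        if "(" in gain_tok:
            gain, baseline = gain_tok.rstrip(")").split("(")
        else:
            gain, baseline = gain_tok, "0"
        gains.append(float(gain) or 200.0)
        baselines.append(int(baseline))
        lead_labels.append(parts[-1] if len(parts) >= 9 else None)
    if len(set(dat_names)) != 1:
        raise FormatError(f"{header_path}: multi-file signal layout unsupported")
    raw = np.fromfile(header_path.with_name(dat_names[0]), dtype="<i2")
    if n_samp is None:
        n_samp = raw.size // n_sig
    data = raw[: n_samp * n_sig].reshape(n_samp, n_sig).T.astype(np.float64)
    data = (data - np.array(baselines)[:, None]) / np.array(gains)[:, None]
    # remap to standard order when the header declares lead names
    if all(lab in LEAD_NAMES for lab in lead_labels if lab):
        if None not in lead_labels and set(lead_labels) == set(LEAD_NAMES):
            order = [lead_labels.index(name_) for name_ in LEAD_NAMES]
            data = data[order]
    return EcgRecord(record_id=name, signal=data, fs=fs)


def write_wfdb(record: EcgRecord, header_path: str | Path, gain: float = 1000.0) -> None:
    """Write a record as a WFDB format-16 header+signal pair (lossy: int16)."""
    header_path = Path(header_path)
    dat_name = header_path.with_suffix(".dat").name
    digital = np.round(record.signal * gain)
    if np.abs(digital).max() > 32767:
        raise FormatError("signal exceeds int16 range at this gain")
    lines = [f"{header_path.stem} {N_LEADS} {record.fs:g} {record.n_samples}"]
    for i, lead in enumerate(LEAD_NAMES):
        lines.append(f"{dat_name} 16 {gain:g}(0)/mV 16 0 0 0 0 {lead}")
    header_path.write_text("\n".join(lines) + "\n")
    with open(header_path.with_name(dat_name), "wb") as fh:
        fh.write(digital.T.astype("<i2").tobytes())


# ---------------------------------------------------------------------------
# Directory-level helpers
# ---------------------------------------------------------------------------

def read_dataset(directory: str | Path) -> tuple[list[EcgRecord], LabelManifest]:
    """Load all ``.mat`` records in a directory plus its ``REFERENCE.csv``.

    Records are labelled with the manifest's FIRST label (the training
    target); secondary labels are attached for audit.
    """
    directory = Path(directory)
    manifest = read_manifest(directory / "REFERENCE.csv")
    records = []
    for record_id in manifest.entries:
        rec = read_cpsc_mat(directory / f"{record_id}.mat", record_id=record_id)
        labels = manifest.entries[record_id]
        rec.label = labels[0]
        rec.secondary_labels = labels[1:]
        records.append(rec)
    return records, manifest


def write_dataset(records: list[EcgRecord], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = LabelManifest()
    for rec in records:
        write_cpsc_mat(rec, directory / f"{rec.record_id}.mat")
        if rec.label is not None:
            manifest.add(rec.record_id, (rec.label, *rec.secondary_labels))
    write_manifest(manifest, directory / "REFERENCE.csv")
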
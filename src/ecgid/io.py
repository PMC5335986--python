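"""Reading, writing and resampling single-lead ECG records.

Records travel as plain two-column CSV (sample index, amplitude in mV) with a
comment header carrying the sampling rate and optional subject/session labels.
WFDB records are supported when the optional ``wfdb`` package is importable.

All records in a study are brought to one uniform sampling rate (360 Hz by
default) with cubic-spline interpolation before any downstream processing, so
that beat windows, wavelet sub-bands and templates are commensurable across
acquisition devices.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["EcgRecord", "read_record", "write_record", "resample_record"]

#: system-wide uniform sampling rate, Hz
DEFAULT_TARGET_FS = 360.0


@dataclass
class EcgRecord:
    """A single-lead ECG trace with metadata.

    Parameters
    ----------
    samples : array of float
        Amplitudes in millivolt, one per sample.
    fs : float
        Sampling rate in Hz, > 0.
    subject_id, session_id : str, optional
        Identity labels used during enrollment/evaluation.
    r_annotations : array of int, optional
        Ground-truth or detected R-peak sample indices, strictly increasing,
        each in ``[0, len(samples))``.
    meta : dict
        Free-form provenance (generator parameters, noise components, ...).
        Never serialised.
    """

    samples: np.ndarray
    fs: float
    subject_id: str | None = None
    session_id: str | None = None
    r_annotations: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        self.fs = float(self.fs)
        if not self.fs > 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if self.r_annotations is not None:
            ann = np.asarray(self.r_annotations, dtype=np.int64)
            if ann.size:
                if np.any(np.diff(ann) <= 0):
                    raise ValueError("r_annotations must be strictly increasing")
                if ann[0] < 0 or ann[-1] >= self.samples.size:
                    raise ValueError("r_annotations out of range [0, n)")
            self.r_annotations = ann

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    def copy(self) -> "EcgRecord":
        return EcgRecord(
            samples=self.samples.copy(),
            fs=self.fs,
            subject_id=self.subject_id,
            session_id=self.session_id,
            r_annotations=None if self.r_annotations is None else self.r_annotations.copy(),
            meta=copy.copy(self.meta),
        )


def _annotation_path(path: Path) -> Path:
    return path.with_suffix(".rpeaks.csv")


def write_record(rec: EcgRecord, path: str | Path) -> Path:
    """Write a record as two-column CSV; R annotations go to a sidecar file.

    Amplitudes are printed with ``%.17g`` so float64 values round-trip
    bit-exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs!r}\n")
        if rec.subject_id is not None:
            fh.write(f"# subject={rec.subject_id}\n")
        if rec.session_id is not None:
            fh.write(f"# session={rec.session_id}\n")
        fh.write("sample_index,amplitude_mV\n")
        for i, v in enumerate(rec.samples):
            fh.write(f"{i},{v:.17g}\n")
    if rec.r_annotations is not None:
        with open(_annotation_path(path), "w") as fh:
            fh.write("r_peak_sample\n")
            for a in rec.r_annotations:
                fh.write(f"{int(a)}\n")
    return path


def _read_csv_record(path: Path) -> EcgRecord:
    fs = None
    subject = None
    session = None
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    key = key.strip().lower()
                    val = val.strip()
                    if key == "fs":
                        fs = float(val)
                    elif key == "subject":
                        subject = val
                    elif key == "session":
                        session = val
                continue
            if line.lower().startswith("sample_index"):
                continue
            parts = line.split(",")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected two columns, got {line!r}")
            try:
                values.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric amplitude {parts[1]!r}"
                ) from exc
    if fs is None:
        raise ValueError(f"{path}: missing required header field 'fs'")
    if not values:
        raise ValueError(f"{path}: no samples found")
    ann = None
    ann_path = _annotation_path(path)
    if ann_path.exists():
        ann = np.loadtxt(ann_path, dtype=np.int64, skiprows=1, ndmin=1)
    return EcgRecord(np.array(values), fs, subject_id=subject, session_id=session, r_annotations=ann)


def _read_wfdb_record(path: Path) -> EcgRecord:
    try:
        import wfdb  # noqa: PLC0415 - optional dependency
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise ImportError(
            "WFDB support requires the optional 'wfdb' package; "
            "install it or convert the record to CSV"
        ) from exc
    record = wfdb.rdrecord(str(path))
    ann = None
    try:
        a = wfdb.rdann(str(path), "atr")
        ann = np.asarray(a.sample, dtype=np.int64)
    except FileNotFoundError:
        pass
    return EcgRecord(
        samples=np.asarray(record.p_signal[:, 0], dtype=np.float64),
        fs=float(record.fs),
        subject_id=record.record_name,
        r_annotations=ann,
    )


def read_record(path: str | Path, format: str = "csv") -> EcgRecord:
    """Read an ECG record from disk.

    ``format="csv"`` expects the dialect written by :func:`write_record` (and
    by the synthetic cohort generator); ``format="wfdb"`` reads a PhysioNet
    record by its path stem when the optional ``wfdb`` package is installed.
    """
    path = Path(path)
    if format == "csv":
        if not path.exists():
            raise FileNotFoundError(path)
        return _read_csv_record(path)
    if format == "wfdb":
        return _read_wfdb_record(path)
    raise ValueError(f"unknown format {format!r}; expected 'csv' or 'wfdb'")


def resample_record(rec: EcgRecord, target_fs: float) -> EcgRecord:
    """Resample to ``target_fs`` with a natural cubic spline.

    The source samples are treated as values on the uniform grid ``k / fs``
    with time origin at sample 0; the output is the spline evaluated on
    ``k / target_fs`` for ``k = 0 ... round(n * target_fs / fs) - 1``.
    R annotations are rescaled by the same ratio and rounded to the nearest
    output sample.
    """
    target_fs = float(target_fs)
    if not target_fs > 0:
        raise ValueError("target_fs must be > 0")
    if target_fs == rec.fs:
        return rec.copy()
    n = rec.samples.size
    if n < 4:
        raise ValueError("cubic-spline resampling needs at least 4 samples")
    ratio = target_fs / rec.fs
    n_out = int(round(n * ratio))
    t_in = np.arange(n) / rec.fs
    spline = CubicSpline(t_in, rec.samples, bc_type="natural")
    t_out = np.arange(n_out) / target_fs
    out = spline(t_out)
    ann = None
    if rec.r_annotations is not None:
        ann = np.round(rec.r_annotations * ratio).astype(np.int64)
        ann = np.clip(ann, 0, n_out - 1)
        if ann.size and np.any(np.diff(ann) <= 0):
            raise ValueError("annotation collision after resampling; rates too disparate")
    return EcgRecord(
        samples=out,
        fs=target_fs,
        subject_id=rec.subject_id,
        session_id=rec.session_id,
        r_annotations=ann,
        meta=dict(rec.meta, resampled_from=rec.fs),
    )
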
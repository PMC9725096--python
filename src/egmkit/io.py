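"""Reading and writing recordings, cohort manifests, and R-peak annotations.

Recordings are multichannel unipolar electrograms stored either as plain CSV
(header row of channel labels, one row per time sample, optional leading
``time``/``t`` column in seconds) or as EDF.  All amplitudes are in
millivolts, all times in seconds, all sample indices 0-based, and intervals
half-open ``[start, end)`` throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "CohortManifest",
    "RPeakAnnotation",
    "read_recording",
    "write_recording",
    "read_manifest",
    "write_manifest",
    "read_annotations",
]

_TIME_COLUMN_NAMES = {"time", "t", "time_s"}


@dataclass
class Recording:
    """A fixed-rate multichannel signal matrix.

    Parameters
    ----------
    samples
        2-D float array, shape ``(n_samples, n_channels)``, millivolts.
    fs
        Sampling rate in Hz.
    channel_labels
        One unique label per column.
    patient_id
        Free-form identifier; empty string when unknown.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (n_samples, n_channels) array")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.shape[1] == 0:
            raise ValueError("Recording must have at least one channel")
        self.channel_labels = [str(c) for c in self.channel_labels]
        if len(self.channel_labels) != self.samples.shape[1]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[1]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label_or_index: str | int) -> np.ndarray:
        """Return one channel as a 1-D array."""
        if isinstance(label_or_index, str):
            idx = self.channel_labels.index(label_or_index)
        else:
            idx = int(label_or_index)
        return self.samples[:, idx]


_LABEL_ALIASES = {
    "term": "Term",
    "nonterm": "NonTerm",
    "non-term": "NonTerm",
    "non_term": "NonTerm",
    "non term": "NonTerm",
}


@dataclass
class CohortManifest:
    """Patient table: id, recording path, termination label, free covariates."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"patient_id", "recording_path", "label"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        ids = self.table["patient_id"].astype(str)
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate patient_id values: {dupes}")
        labels = []
        for raw in self.table["label"]:
            key = str(raw).strip().lower()
            if key not in _LABEL_ALIASES:
                raise ValueError(f"unknown termination label: {raw!r}")
            labels.append(_LABEL_ALIASES[key])
        self.table = self.table.assign(patient_id=ids, label=labels)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.table["patient_id"])

    @property
    def labels(self) -> list[str]:
        return list(self.table["label"])

    def counts(self) -> tuple[int, int]:
        """(n_term, n_nonterm)."""
        lab = self.table["label"]
        return int((lab == "Term").sum()), int((lab == "NonTerm").sum())

    def covariate_columns(self) -> list[str]:
        skip = {"patient_id", "recording_path", "label"}
        return [c for c in self.table.columns if c not in skip]


@dataclass
class RPeakAnnotation:
    """Sorted R-peak times (seconds) for one patient, for QRS subtraction."""

    patient_id: str
    peak_times_s: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        t = np.asarray(self.peak_times_s, dtype=float)
        if t.size and not np.all(np.diff(t) > 0):
            raise ValueError("peak times must be strictly increasing")
        if t.size and t[0] < 0:
            raise ValueError("peak times must be non-negative")
        self.peak_times_s = t


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return "edf"
    return "csv"


def read_recording(
    path: str | Path,
    format: str | None = None,
    fs: float | None = None,
    patient_id: str = "",
) -> Recording:
    """Read a recording from CSV or EDF.

    For CSV, ``fs`` must be supplied unless the file has a leading time
    column (named ``time``/``t``/``time_s``), from which the rate is taken as
    ``1/median(diff(time))``.  When both are available the timestamps are only
    used to validate ``fs`` (median step within 1%).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = _infer_format(path, format)
    if fmt == "edf":
        return _read_edf(path, patient_id=patient_id)
    if fmt != "csv":
        raise ValueError(f"unknown recording format: {fmt!r}")

    df = pd.read_csv(path)
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise ValueError(f"{path}: empty recording file")
    bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if bad or df.isna().any().any():
        raise ValueError(f"{path}: non-numeric or missing cells (columns {bad})")

    first = str(df.columns[0]).strip().lower()
    if first in _TIME_COLUMN_NAMES:
        t = df.iloc[:, 0].to_numpy(dtype=float)
        df = df.iloc[:, 1:]
        if df.shape[1] == 0:
            raise ValueError(f"{path}: only a time column, no channels")
        if len(t) < 2:
            raise ValueError(f"{path}: need >= 2 samples to use a time column")
        dt = float(np.median(np.diff(t)))
        if dt <= 0:
            raise ValueError(f"{path}: time column is not increasing")
        fs_inferred = 1.0 / dt
        if fs is None:
            fs = fs_inferred
        elif abs(fs_inferred - fs) > 0.01 * fs:
            raise ValueError(
                f"{path}: time column implies fs={fs_inferred:.6g} Hz, "
                f"more than 1% away from declared fs={fs:.6g} Hz"
            )
    if fs is None:
        raise ValueError(
            f"{path}: fs not given and no time column to infer it from"
        )
    return Recording(
        samples=df.to_numpy(dtype=float),
        fs=float(fs),
        channel_labels=[str(c) for c in df.columns],
        patient_id=patient_id,
    )


def write_recording(
    rec: Recording,
    path: str | Path,
    format: str | None = None,
    include_time: bool = False,
) -> None:
    """Write a recording as CSV (lossless to ~1e-12 relative) or EDF (16-bit)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "edf":
        _write_edf(rec, path)
        return
    if fmt != "csv":
        raise ValueError(f"unknown recording format: {fmt!r}")
    df = pd.DataFrame(rec.samples, columns=rec.channel_labels)
    if include_time:
        df.insert(0, "time", np.arange(rec.n_samples) / rec.fs)
    df.to_csv(path, index=False, float_format="%.12g")


# --- EDF ------------------------------------------------------------------
# Reading goes through mne (imported lazily: it is heavy and only needed for
# EDF).  Writing uses a minimal EDF implementation: no installed package in
# this environment writes EDF.  One 1-second data record per second of
# signal; the sampling rate must therefore be a whole number and recordings
# are padded to a whole number of seconds (documented quantization).

def _read_edf(path: Path, patient_id: str = "") -> Recording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="ERROR")
    data = raw.get_data()  # (n_channels, n_samples), SI units (V) for voltages
    fs = float(raw.info["sfreq"])
    # stored physical unit is mV; mne rescales voltage channels to volts
    return Recording(
        samples=data.T * 1e3,
        fs=fs,
        channel_labels=list(raw.ch_names),
        patient_id=patient_id,
    )


def _write_edf(rec: Recording, path: Path) -> None:
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs_i = int(round(fs))
    n_ch = rec.n_channels
    n_rec = int(np.ceil(rec.n_samples / fs_i))
    if n_rec == 0:
        raise ValueError("cannot write an empty recording")
    padded = np.zeros((n_rec * fs_i, n_ch))
    padded[: rec.n_samples] = rec.samples

    phys_min = np.minimum(padded.min(axis=0), -1e-6)
    phys_max = np.maximum(padded.max(axis=0), 1e-6)
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(
        np.round((padded - phys_min) * scale) + dig_min, dig_min, dig_max
    ).astype("<i2")

    def fixed(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    header = b"".join(
        [
            fixed("0", 8),
            fixed(rec.patient_id or "X", 80),
            fixed("egmkit recording", 80),
            fixed("01.01.00", 8),
            fixed("00.00.00", 8),
            fixed(str(256 * (1 + n_ch)), 8),
            fixed("", 44),
            fixed(str(n_rec), 8),
            fixed("1", 8),  # record duration, seconds
            fixed(str(n_ch), 4),
        ]
    )
    sig_header = b"".join(
        [
            b"".join(fixed(lbl, 16) for lbl in rec.channel_labels),
            b"".join(fixed("EGM", 80) for _ in range(n_ch)),
            b"".join(fixed("mV", 8) for _ in range(n_ch)),
            b"".join(fixed(f"{phys_min[c]:.6g}"[:8], 8) for c in range(n_ch)),
            b"".join(fixed(f"{phys_max[c]:.6g}"[:8], 8) for c in range(n_ch)),
            b"".join(fixed(str(dig_min), 8) for _ in range(n_ch)),
            b"".join(fixed(str(dig_max), 8) for _ in range(n_ch)),
            b"".join(fixed("", 80) for _ in range(n_ch)),
            b"".join(fixed(str(fs_i), 8) for _ in range(n_ch)),
            b"".join(fixed("", 32) for _ in range(n_ch)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_rec):
            block = digital[r * fs_i : (r + 1) * fs_i]  # (fs, n_ch)
            fh.write(block.T.tobytes())


# --- manifests and annotations --------------------------------------------

def read_manifest(path: str | Path) -> CohortManifest:
    """Read a cohort manifest CSV (patient_id, recording_path, label, ...)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    return CohortManifest(pd.read_csv(path))


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    manifest.table.to_csv(path, index=False)


def read_annotations(path: str | Path) -> dict[str, RPeakAnnotation]:
    """Read R-peak annotations (CSV: patient_id, peak_time_s) keyed by patient."""
    df = pd.read_csv(path)
    required = {"patient_id", "peak_time_s"}
    if missing := required - set(df.columns):
        raise ValueError(f"annotation file missing columns: {sorted(missing)}")
    out: dict[str, RPeakAnnotation] = {}
    for pid, grp in df.groupby("patient_id", sort=False):
        out[str(pid)] = RPeakAnnotation(
            patient_id=str(pid),
            peak_times_s=np.sort(grp["peak_time_s"].to_numpy(dtype=float)),
        )
    return out
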
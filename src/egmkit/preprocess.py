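"""Filtering and ventricular far-field removal.

The EQI front end is fixed: a 4th-order Butterworth high-pass at 2.5 Hz and
low-pass at 30 Hz (together the 2.5-30 Hz band-pass), plus a 4th-order
Butterworth band-stop between 55 and 65 Hz against mains pickup.  All
filters run zero-phase (forward-backward) by default, so deflection timing
is preserved; the effective magnitude response is then the square of the
single-pass design.

QRS far-field removal follows the average-template approach: the signal is
averaged across windows around externally supplied R-peak times and that
template is subtracted at each window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import Recording, RPeakAnnotation

__all__ = [
    "FilterSpec",
    "apply_filter",
    "eqi_prefilter",
    "qrs_subtract",
    "detect_farfield_peaks",
]

#: window around each R peak used for template subtraction, ms
DEFAULT_QRS_WINDOW_MS = (-100.0, 150.0)


@dataclass(frozen=True)
class FilterSpec:
    """One Butterworth stage.

    ``kind`` is ``highpass``/``lowpass`` (uses ``low_hz``/``high_hz``
    respectively), ``bandpass`` or ``bandstop`` (uses both corners).
    ``order`` is the order of the single-pass design; with
    ``zero_phase=True`` the filter is applied forward and backward.
    """

    kind: str
    low_hz: float | None = None
    high_hz: float | None = None
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in {"highpass", "lowpass", "bandpass", "bandstop"}:
            raise ValueError(f"unknown filter kind: {self.kind!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def corners(self) -> tuple[float, ...]:
        if self.kind == "highpass":
            if self.low_hz is None:
                raise ValueError("highpass needs low_hz")
            return (self.low_hz,)
        if self.kind == "lowpass":
            if self.high_hz is None:
                raise ValueError("lowpass needs high_hz")
            return (self.high_hz,)
        if self.low_hz is None or self.high_hz is None:
            raise ValueError(f"{self.kind} needs both corners")
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")
        return (self.low_hz, self.high_hz)

    def sos(self, fs: float) -> np.ndarray:
        corners = self.corners()
        if max(corners) >= fs / 2:
            raise ValueError(
                f"corner {max(corners)} Hz at or above Nyquist ({fs / 2} Hz)")
        wn = corners[0] if len(corners) == 1 else list(corners)
        return sps.butter(self.order, wn, btype=self.kind, fs=fs,
                          output="sos")


def _filter_array(x: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    sos = spec.sos(fs)
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x, axis=0)
    return sps.sosfilt(sos, x, axis=0)


def apply_filter(rec: Recording, spec: FilterSpec) -> Recording:
    """Filter every channel; output has the same shape and metadata."""
    min_len = 3 * (2 * spec.order + 1)  # sosfiltfilt padding needs headroom
    if rec.n_samples <= min_len:
        raise ValueError(
            f"recording too short to filter: {rec.n_samples} samples, "
            f"need > {min_len}")
    return Recording(_filter_array(rec.samples, spec, rec.fs), rec.fs,
                     list(rec.channel_labels), rec.patient_id)


def eqi_prefilter(rec: Recording, zero_phase: bool = True,
                  notch: tuple[float, float] = (55.0, 65.0)) -> Recording:
    """Mandatory EQI front end: 2.5 Hz HP + 30 Hz LP + 55-65 Hz band-stop.

    All stages are 4th-order Butterworth; ``notch=(45, 55)`` adapts the
    band-stop to 50 Hz mains regions.
    """
    if rec.fs < 2 * notch[1]:
        raise ValueError(
            f"fs={rec.fs} Hz too low for the {notch[0]}-{notch[1]} Hz band-stop")
    stages = [
        FilterSpec("highpass", low_hz=2.5, order=4, zero_phase=zero_phase),
        FilterSpec("lowpass", high_hz=30.0, order=4, zero_phase=zero_phase),
        FilterSpec("bandstop", low_hz=notch[0], high_hz=notch[1], order=4,
                   zero_phase=zero_phase),
    ]
    x = rec.samples
    for spec in stages:
        x = _filter_array(x, spec, rec.fs)
    return Recording(x, rec.fs, list(rec.channel_labels), rec.patient_id)


def qrs_subtract(
    rec: Recording,
    ann: RPeakAnnotation,
    window_ms: tuple[float, float] = DEFAULT_QRS_WINDOW_MS,
) -> Recording:
    """Remove the ventricular far field by average-template subtraction.

    Per channel: windows ``[peak + window_ms[0], peak + window_ms[1])`` are
    extracted around each annotated R peak, demeaned, and averaged into a
    template, which is then subtracted at every used window.  Peaks whose
    windows fall outside the recording are dropped; a peak overlapping the
    previous one's window is skipped with a warning.
    """
    lo_s, hi_s = window_ms[0] / 1000.0, window_ms[1] / 1000.0
    if hi_s <= lo_s:
        raise ValueError("window_ms must be an increasing pair")
    peaks = np.asarray(ann.peak_times_s, dtype=float)
    if peaks.size < 3:
        raise ValueError(
            f"need >= 3 annotated R peaks for a template, got {peaks.size}")

    n = rec.n_samples
    w_lo = int(round(lo_s * rec.fs))
    w_hi = int(round(hi_s * rec.fs))
    span = w_hi - w_lo

    starts: list[int] = []
    last_end = -1
    n_skipped = 0
    for t in peaks:
        s = int(round(t * rec.fs)) + w_lo
        if s < 0 or s + span > n:
            continue
        if s < last_end:
            n_skipped += 1
            continue
        starts.append(s)
        last_end = s + span
    if n_skipped:
        warnings.warn(
            f"qrs_subtract: skipped {n_skipped} R peaks overlapping the "
            f"previous window", stacklevel=2)
    if len(starts) < 3:
        raise ValueError("fewer than 3 usable R-peak windows inside the record")

    out = rec.samples.copy()
    windows = np.stack([rec.samples[s:s + span] for s in starts])  # (b, span, c)
    template = (windows - windows.mean(axis=1, keepdims=True)).mean(axis=0)
    for s in starts:
        out[s:s + span] -= template
    return Recording(out, rec.fs, list(rec.channel_labels), rec.patient_id)


def detect_farfield_peaks(channel: np.ndarray, fs: float,
                          min_rate_bpm: float = 40.0,
                          threshold_frac: float = 0.5) -> np.ndarray:
    """Convenience threshold detector for far-field peaks on a reference channel.

    Not part of the validated pipeline: R-peak times normally come from an
    annotation file.  Peaks are local maxima of the absolute signal above
    ``threshold_frac`` of its maximum, at least ``60/min_rate_bpm`` s apart.
    """
    x = np.abs(np.asarray(channel, dtype=float))
    distance = int(fs * 60.0 / min_rate_bpm / 2.0)
    locs, _ = sps.find_peaks(x, height=threshold_frac * x.max(),
                             distance=max(distance, 1))
    return locs / fs
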
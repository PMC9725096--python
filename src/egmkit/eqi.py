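"""Electrogram quality index (EQI).

The EQI scores how cleanly a single large dv/dt peak — the signature of
local tissue activation — stands out in each activation cycle.  Pipeline
per channel:

1. band-limit the electrogram (2.5-30 Hz band-pass + 55-65 Hz band-stop,
   zero-phase; see :mod:`egmkit.preprocess`);
2. estimate the cycle period ``T`` as the lag of the first non-zero-time
   peak of the autocorrelation of the smoothed signal;
3. differentiate (first difference x fs) and cut the usable span into
   consecutive intervals of width ``T``;
4. per interval compute ``Q_i = (beta - mean(gamma_j)) / beta`` where
   ``beta`` is the interval's dv/dt maximum and the ``gamma_j`` are the
   other positive local maxima; a single clean peak gives ``Q_i = 1``, two
   equal peaks give ``Q_i = 0``;
5. the channel EQI is the mean ``Q_i`` over the ~300 intervals of a 60 s
   record, and the patient EQI the mean over channels.

The EQI has no tunable analysis parameters beyond physiologic period
bounds; by construction it lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .io import Recording
from .preprocess import FilterSpec, _filter_array, eqi_prefilter

__all__ = [
    "EQIConfig",
    "PeriodEstimate",
    "IntervalQ",
    "ChannelEQIResult",
    "estimate_period",
    "interval_q",
    "eqi_channel",
    "eqi_recording",
    "eqi_patient",
]


@dataclass(frozen=True)
class EQIConfig:
    """EQI pipeline settings.

    ``T_min_s``/``T_max_s`` bound the physiologic fibrillatory period
    (default 100-400 ms) so the autocorrelation peak cannot lock onto
    harmonics or sub-harmonics.  ``acf_smooth_hz`` is the zero-phase
    low-pass applied before the autocorrelation; ``prominence`` is the
    minimum peak prominence as a fraction of the zero-lag value.
    ``edge_trim_s`` drops filter transients at both ends;
    ``start_offset_s`` shifts the first interval within ``[0, T)`` (the
    EQI is insensitive to it).
    """

    T_min_s: float = 0.10
    T_max_s: float = 0.40
    acf_smooth_hz: float = 20.0
    acf_smooth_order: int = 4
    prominence: float = 0.08
    edge_trim_s: float = 0.5
    start_offset_s: float = 0.0
    prefiltered: bool = False


@dataclass(frozen=True)
class PeriodEstimate:
    T_s: float
    acf_peak_lag_samples: int
    acf_peak_value: float


@dataclass(frozen=True)
class IntervalQ:
    start_s: float
    end_s: float
    beta: float
    gammas: tuple[float, ...]
    q: float
    no_activation: bool = False  # beta <= 0: no positive deflection at all


@dataclass(frozen=True)
class ChannelEQIResult:
    eqi: float
    T_s: float
    n_intervals: int
    interval_qs: tuple[IntervalQ, ...] = field(default=(), repr=False)
    channel_label: str = ""


def _autocorrelation(x: np.ndarray) -> np.ndarray:
    """Biased autocorrelation for non-negative lags, normalized to acf[0]=1."""
    x = x - x.mean()
    n = x.size
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.abs(np.fft.rfft(x, nfft)) ** 2
    acf = np.fft.irfft(spec)[:n]
    if acf[0] <= 0:
        raise ValueError("zero-variance signal: no autocorrelation structure")
    return acf / acf[0]


def estimate_period(channel: np.ndarray, fs: float, T_min_s: float = 0.10,
                    T_max_s: float = 0.40, smooth_hz: float = 20.0,
                    smooth_order: int = 4,
                    prominence: float = 0.08) -> PeriodEstimate:
    """Cycle period from the first non-zero-lag autocorrelation peak.

    The channel (assumed already prefiltered) is smoothed by a zero-phase
    Butterworth low-pass at ``smooth_hz`` before the autocorrelation.  The
    period is the lag of the highest-valued autocorrelation peak inside
    ``[T_min_s, T_max_s]`` among peaks with prominence at least
    ``prominence`` (as a fraction of the zero-lag value).  Because the
    biased autocorrelation decays with lag, the fundamental period peak is
    the tallest in-band peak, while sidelobes and cross-terms between
    signal components (which can *precede* it) stay well below it.
    """
    x = np.asarray(channel, dtype=float)
    if x.size < 2 * int(T_max_s * fs):
        raise ValueError("signal shorter than two maximal periods")
    spec = FilterSpec("lowpass", high_hz=smooth_hz, order=smooth_order,
                      zero_phase=True)
    smoothed = _filter_array(x, spec, fs)
    acf = _autocorrelation(smoothed)

    lag_min = max(int(np.floor(T_min_s * fs)), 1)
    lag_max = int(np.ceil(T_max_s * fs))
    # prominence evaluated on the full positive-lag ACF so shoulders inside
    # the window are not inflated by the restricted view
    peaks, props = sps.find_peaks(acf[1:], prominence=prominence)
    peaks = peaks + 1
    band = (peaks >= lag_min) & (peaks <= lag_max)
    in_band = peaks[band]
    if in_band.size == 0:
        raise ValueError(
            f"no autocorrelation peak with prominence >= {prominence} in "
            f"[{T_min_s}, {T_max_s}] s — widen the period bounds or check "
            f"that the signal is periodic")
    lag = int(in_band[np.argmax(acf[in_band])])
    return PeriodEstimate(T_s=lag / fs, acf_peak_lag_samples=lag,
                          acf_peak_value=float(acf[lag]))


def _positive_local_maxima(x: np.ndarray) -> np.ndarray:
    """Values of positive local maxima (plateaus count once)."""
    peaks, _ = sps.find_peaks(x)  # strict neighbors; plateau -> single peak
    vals = x[peaks]
    return vals[vals > 0]


def interval_q(dvdt_segment: np.ndarray, start_s: float = 0.0,
               end_s: float = 0.0) -> IntervalQ:
    """Q statistic of one analysis interval of the dv/dt trace.

    ``beta`` is the global maximum of the segment (boundary samples count);
    the ``gamma_j`` are the positive local maxima excluding one occurrence
    attaining ``beta``.  ``Q = (beta - mean(gamma)) / beta``, 1 when no
    other positive maximum exists, 0 (flagged) when ``beta <= 0``.
    """
    x = np.asarray(dvdt_segment, dtype=float)
    if x.size == 0:
        raise ValueError("empty dv/dt segment")
    beta = float(x.max())
    if beta <= 0:
        return IntervalQ(start_s, end_s, beta, (), 0.0, no_activation=True)
    gammas = _positive_local_maxima(x)
    at_beta = np.flatnonzero(gammas >= beta)
    if at_beta.size:  # drop one occurrence of the maximum itself
        gammas = np.delete(gammas, at_beta[0])
    if gammas.size == 0:
        return IntervalQ(start_s, end_s, beta, (), 1.0)
    q = (beta - float(gammas.mean())) / beta
    return IntervalQ(start_s, end_s, beta, tuple(gammas), q)


def eqi_channel(channel: np.ndarray, fs: float,
                cfg: EQIConfig = EQIConfig(),
                channel_label: str = "") -> ChannelEQIResult:
    """Full single-channel EQI pipeline."""
    x = np.asarray(channel, dtype=float)
    if not cfg.prefiltered:
        rec = eqi_prefilter(Recording(x[:, None], fs, ["ch"]))
        x = rec.samples[:, 0]
    period = estimate_period(x, fs, T_min_s=cfg.T_min_s, T_max_s=cfg.T_max_s,
                             smooth_hz=cfg.acf_smooth_hz,
                             smooth_order=cfg.acf_smooth_order,
                             prominence=cfg.prominence)
    dvdt = np.diff(x) * fs

    t_len = period.acf_peak_lag_samples
    trim = int(round(cfg.edge_trim_s * fs))
    offset = int(round((cfg.start_offset_s % period.T_s) * fs))
    start = trim + offset
    stop = min(x.size - trim, dvdt.size)  # usable span [trim, n - trim)
    n_intervals = (stop - start) // t_len
    if n_intervals < 1:
        raise ValueError("usable span shorter than one period")
    qs = []
    for k in range(n_intervals):
        lo = start + k * t_len
        seg = dvdt[lo:lo + t_len]
        qs.append(interval_q(seg, start_s=lo / fs, end_s=(lo + t_len) / fs))
    return ChannelEQIResult(
        eqi=float(np.mean([iq.q for iq in qs])), T_s=period.T_s,
        n_intervals=n_intervals, interval_qs=tuple(qs),
        channel_label=channel_label)


def eqi_recording(rec: Recording, cfg: EQIConfig = EQIConfig()
                  ) -> tuple[list[ChannelEQIResult], list[str]]:
    """EQI of every channel; channels with no estimable period are excluded.

    Returns the per-channel results and the labels of excluded channels.
    """
    filtered = rec if cfg.prefiltered else eqi_prefilter(rec)
    ch_cfg = replace(cfg, prefiltered=True)
    results, failed = [], []
    for c, label in enumerate(filtered.channel_labels):
        try:
            results.append(eqi_channel(filtered.samples[:, c], filtered.fs,
                                       cfg=ch_cfg, channel_label=label))
        except ValueError:
            failed.append(label)
    return results, failed


def eqi_patient(channel_results: list[ChannelEQIResult]) -> float:
    """Patient EQI: arithmetic mean of the channel EQIs."""
    if not channel_results:
        raise ValueError("need at least one channel EQI")
    return float(np.mean([r.eqi for r in channel_results]))
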
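"""Synthetic unipolar-electrogram generator.

Emulates the qualitative morphology of basket-catheter atrial fibrillation
recordings: a quasi-periodic train of biphasic activation deflections
(mean cycle length ~200 ms, i.e. ~5 Hz), per-beat jitter in timing and
amplitude, optional fractionated (multi-deflection) complexes, broadband
noise, 60 Hz mains interference, and a slower, wider ventricular far-field
deflection train.  Organized regimes (low jitter, single deflections) stand
in for patients whose fibrillation terminated during ablation; disorganized
regimes (high jitter, fractionation, more noise) for those who did not.

The primary deflection is a derivative-of-Gaussian: biphasic with a single
sharp dv/dt extremum, the classical shape of a unipolar activation.
All randomness flows through numpy SeedSequences spawned per (patient,
channel), so cohorts are reproducible channel-by-channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import CohortManifest, Recording, write_recording

__all__ = [
    "EgmSimParams",
    "CohortSimParams",
    "simulate_channel",
    "simulate_recording",
    "simulate_cohort",
    "simulate_cohort_recordings",
    "organized_params",
    "disorganized_params",
    "regime_suite",
]


@dataclass(frozen=True)
class EgmSimParams:
    """Parameters of one synthetic electrogram channel.

    Units: times in ms where suffixed, amplitudes in mV, rates in Hz/bpm.
    ``cl_jitter_cv`` and ``amp_cv`` are coefficients of variation of the
    per-beat cycle length and amplitude.  ``n_fractionated`` extra
    deflections of relative amplitude ``frac_amp_ratio`` are placed at
    uniform offsets within ``frac_offset_ms_range`` after each activation.
    """

    fs: float = 1000.0
    duration_s: float = 60.0
    cycle_length_ms: float = 200.0
    cl_jitter_cv: float = 0.05
    deflection_width_ms: float = 4.0
    amp_mv: float = 1.0
    amp_cv: float = 0.1
    n_fractionated: int = 0
    frac_amp_ratio: float = 0.6
    frac_offset_ms_range: tuple[float, float] = (20.0, 120.0)
    recovery_amp_ratio: float = 0.3
    recovery_width_ms: float = 40.0
    recovery_delay_ms: float = 40.0
    noise_sd_mv: float = 0.05
    mains_amp_mv: float = 0.02
    mains_hz: float = 60.0
    farfield_amp_mv: float = 0.0
    farfield_rate_bpm: float = 70.0
    farfield_width_ms: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.fs, self.duration_s, self.cycle_length_ms,
               self.deflection_width_ms) <= 0:
            raise ValueError("fs, duration_s, cycle_length_ms and "
                             "deflection_width_ms must be positive")
        if self.cl_jitter_cv < 0 or self.amp_cv < 0:
            raise ValueError("cl_jitter_cv and amp_cv must be >= 0")
        if self.n_fractionated < 0:
            raise ValueError("n_fractionated must be >= 0")


@dataclass(frozen=True)
class CohortSimParams:
    """Two-group synthetic cohort: organized (Term) vs disorganized (NonTerm)."""

    n_term: int = 17
    n_nonterm: int = 25
    term_params: EgmSimParams = field(default_factory=lambda: organized_params())
    nonterm_params: EgmSimParams = field(
        default_factory=lambda: disorganized_params())
    between_patient_cv: float = 0.05
    n_channels: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_term < 1 or self.n_nonterm < 1:
            raise ValueError("need at least one patient per group")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")


def organized_params(**overrides) -> EgmSimParams:
    """Template for the organized (terminating) phenotype.

    Regular activation (0.5% per-beat cycle-length CV), clean single
    deflections, low noise — sharp periodic trains with strong spectral
    harmonics.  Under renewal-process beat times the timing drift is
    cumulative, so the per-beat CV must stay small (~4 ms drift across a
    4 s spectral window) for the harmonics to remain coherent, as an
    organized fibrillation driver keeps them.
    """
    defaults = dict(cl_jitter_cv=0.005, n_fractionated=0, noise_sd_mv=0.03,
                    mains_amp_mv=0.02)
    defaults.update(overrides)
    return EgmSimParams(**defaults)


def disorganized_params(**overrides) -> EgmSimParams:
    """Template for the disorganized (non-terminating) phenotype.

    Irregular activation (10% per-beat cycle-length CV), fractionated
    complexes (two extra deflections at 80% amplitude), higher noise — a
    broad single spectral peak with the harmonics decohered away.
    """
    defaults = dict(cl_jitter_cv=0.10, n_fractionated=2, frac_amp_ratio=0.8,
                    noise_sd_mv=0.08, mains_amp_mv=0.02)
    defaults.update(overrides)
    return EgmSimParams(**defaults)


def _deflection(t_rel_s: np.ndarray, sigma_s: float, amp: float) -> np.ndarray:
    # derivative of a Gaussian, scaled so the extrema have magnitude `amp`;
    # negative lobe leads (classical unipolar activation polarity)
    u = t_rel_s / sigma_s
    return amp * u * np.exp(0.5 - 0.5 * u * u)


def _add_train(signal: np.ndarray, fs: float, times_s: np.ndarray,
               amps: np.ndarray, sigma_s: float) -> None:
    """Add deflections in place, each evaluated on a +-5 sigma support."""
    n = signal.size
    half = int(np.ceil(5 * sigma_s * fs))
    for t0, a in zip(times_s, amps):
        c = int(round(t0 * fs))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        if lo >= hi:
            continue
        t_rel = (np.arange(lo, hi) / fs) - t0
        signal[lo:hi] += _deflection(t_rel, sigma_s, a)


def _add_slow_wave(signal: np.ndarray, fs: float, times_s: np.ndarray,
                   amps: np.ndarray, sigma_s: float) -> None:
    """Add monophasic Gaussian lobes in place (repolarization-like waves)."""
    n = signal.size
    half = int(np.ceil(5 * sigma_s * fs))
    for t0, a in zip(times_s, amps):
        c = int(round(t0 * fs))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        if lo >= hi:
            continue
        u = ((np.arange(lo, hi) / fs) - t0) / sigma_s
        signal[lo:hi] += a * np.exp(-0.5 * u * u)


def _beat_times(rng: np.random.Generator, p: EgmSimParams) -> np.ndarray:
    """Renewal process of activation times; gaps floored at 2 deflection widths."""
    cl_s = p.cycle_length_ms / 1000.0
    min_gap = 2.0 * p.deflection_width_ms / 1000.0
    times = []
    t = cl_s / 2.0  # first activation away from the record edge
    while t < p.duration_s:
        times.append(t)
        gap = cl_s if p.cl_jitter_cv == 0 else rng.normal(
            cl_s, p.cl_jitter_cv * cl_s)
        t += max(gap, min_gap)
    return np.asarray(times)


def simulate_channel(p: EgmSimParams,
                     rng: np.random.Generator | None = None) -> Recording:
    """Simulate one electrogram channel; deterministic given ``p.seed``."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(p.seed))
    n = int(round(p.duration_s * p.fs))
    signal = np.zeros(n)
    t_axis = np.arange(n) / p.fs

    beats = _beat_times(rng, p)
    amps = p.amp_mv * np.ones(beats.size)
    if p.amp_cv > 0:
        amps *= np.maximum(rng.normal(1.0, p.amp_cv, beats.size), 0.05)
    sigma_s = p.deflection_width_ms / 1000.0
    _add_train(signal, p.fs, beats, amps, sigma_s)

    # slower repolarization lobe after each activation: carries the
    # low-frequency power that makes the spectral peak sit at the
    # activation rate (1/CL) rather than at the sharp deflection's band
    if p.recovery_amp_ratio > 0:
        _add_slow_wave(signal, p.fs,
                       beats + p.recovery_delay_ms / 1000.0,
                       -amps * p.recovery_amp_ratio,
                       p.recovery_width_ms / 1000.0)

    if p.n_fractionated > 0:
        lo, hi = p.frac_offset_ms_range
        for _ in range(p.n_fractionated):
            offsets = rng.uniform(lo / 1000.0, hi / 1000.0, beats.size)
            _add_train(signal, p.fs, beats + offsets,
                       amps * p.frac_amp_ratio, sigma_s)

    if p.farfield_amp_mv > 0:
        ff_cl = 60.0 / p.farfield_rate_bpm
        ff_times = np.arange(ff_cl / 2.0, p.duration_s, ff_cl)
        _add_train(signal, p.fs, ff_times,
                   np.full(ff_times.size, p.farfield_amp_mv),
                   p.farfield_width_ms / 1000.0)

    if p.mains_amp_mv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        signal += p.mains_amp_mv * np.sin(2 * np.pi * p.mains_hz * t_axis + phase)
    if p.noise_sd_mv > 0:
        signal += rng.normal(0.0, p.noise_sd_mv, n)

    return Recording(signal[:, None], p.fs, ["ch1"])


def simulate_recording(p: EgmSimParams, n_channels: int,
                       seed: int | None = None) -> Recording:
    """Simulate a multichannel recording: independent channels, shared params.

    Channel ``c`` draws from ``SeedSequence(seed, spawn_key=(c,))`` so any
    channel can be regenerated in isolation.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if seed is None:
        seed = p.seed
    cols = []
    for c in range(n_channels):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(c,)))
        cols.append(simulate_channel(p, rng=rng).samples[:, 0])
    return Recording(np.column_stack(cols), p.fs,
                     [f"ch{c + 1}" for c in range(n_channels)])


def _perturb(p: EgmSimParams, cv: float, rng: np.random.Generator) -> EgmSimParams:
    """Between-patient variation: jitter continuous template fields by cv."""
    if cv <= 0:
        return p
    def j(x: float, lo: float = 1e-6) -> float:
        return max(float(x * rng.normal(1.0, cv)), lo)
    return replace(
        p,
        cycle_length_ms=j(p.cycle_length_ms),
        cl_jitter_cv=max(float(p.cl_jitter_cv * rng.normal(1.0, cv)), 0.0),
        amp_mv=j(p.amp_mv),
        noise_sd_mv=max(float(p.noise_sd_mv * rng.normal(1.0, cv)), 0.0),
    )


def simulate_cohort_recordings(
    p: CohortSimParams,
) -> list[tuple[str, str, Recording]]:
    """Generate all cohort recordings in memory.

    Returns ``(patient_id, label, recording)`` triples, Term patients first.
    Patient ``i`` uses ``SeedSequence(seed, spawn_key=(i,))`` for its template
    perturbation and ``spawn_key=(i, c)`` for channel ``c``.
    """
    out = []
    groups = [("Term", p.term_params, p.n_term),
              ("NonTerm", p.nonterm_params, p.n_nonterm)]
    i = 0
    for label, template, count in groups:
        for _ in range(count):
            rng = np.random.default_rng(
                np.random.SeedSequence(p.seed, spawn_key=(i,)))
            params = _perturb(template, p.between_patient_cv, rng)
            cols = []
            for c in range(p.n_channels):
                ch_rng = np.random.default_rng(
                    np.random.SeedSequence(p.seed, spawn_key=(i, c)))
                cols.append(simulate_channel(params, rng=ch_rng).samples[:, 0])
            pid = f"{label.lower()}_{i:03d}"
            rec = Recording(np.column_stack(cols), params.fs,
                            [f"ch{c + 1}" for c in range(p.n_channels)],
                            patient_id=pid)
            out.append((pid, label, rec))
            i += 1
    return out


def simulate_cohort(p: CohortSimParams, out_dir: str | Path) -> CohortManifest:
    """Simulate a cohort and write one CSV recording per patient + manifest."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for pid, label, rec in simulate_cohort_recordings(p):
        rel = f"{pid}.csv"
        write_recording(rec, out_dir / rel)
        rows.append({"patient_id": pid, "recording_path": rel, "label": label})
    manifest = CohortManifest(pd.DataFrame(rows))
    manifest.table.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def regime_suite(n: int = 100, seed: int = 0,
                 duration_s: float = 60.0) -> list[EgmSimParams]:
    """A randomized suite of channel parameters spanning the generator regimes.

    Draws cycle length 150-250 ms, jitter CV 0-0.25, 0-3 fractionated
    deflections, noise 0.01-0.15 mV, mains 0-0.1 mV — from fully organized
    to heavily disorganized signals.  Used for range-bound and robustness
    checks across the whole operating envelope.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(999,)))
    suite = []
    for k in range(n):
        suite.append(EgmSimParams(
            duration_s=duration_s,
            cycle_length_ms=float(rng.uniform(150, 250)),
            cl_jitter_cv=float(rng.uniform(0.0, 0.25)),
            deflection_width_ms=float(rng.uniform(3.0, 8.0)),
            amp_mv=float(rng.uniform(0.5, 2.0)),
            amp_cv=float(rng.uniform(0.0, 0.3)),
            n_fractionated=int(rng.integers(0, 4)),
            frac_amp_ratio=float(rng.uniform(0.3, 1.0)),
            noise_sd_mv=float(rng.uniform(0.01, 0.15)),
            mains_amp_mv=float(rng.uniform(0.0, 0.1)),
            farfield_amp_mv=float(rng.choice([0.0, 0.2, 0.4])),
            seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return suite
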
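"""Shared fixtures: analytic electrogram trains and the randomized regime suite."""

import numpy as np
import pytest

from egmkit.synthetic import EgmSimParams, regime_suite, simulate_channel

#: noise-free deterministic base settings shared by the analytic fixtures
_NOISE_FREE = dict(cl_jitter_cv=0.0, amp_cv=0.0, noise_sd_mv=0.0,
                   mains_amp_mv=0.0)


@pytest.fixture(scope="session")
def clean_train_band_limited():
    """Noise-free single-deflection train, 200 ms cycle length.

    Deflection sigma 15 ms and no recovery lobe keep the waveform band
    limited inside the 2.5-30 Hz analysis band, so the EQI pipeline sees a
    single clean dv/dt peak per cycle with no filter-ringing artifacts.
    """
    p = EgmSimParams(n_fractionated=0, deflection_width_ms=15.0,
                     recovery_amp_ratio=0.0, **_NOISE_FREE)
    return simulate_channel(p).samples[:, 0], p.fs


@pytest.fixture(scope="session")
def dual_train_band_limited():
    """Noise-free train with two equal deflections per 200 ms cycle (70 ms apart)."""
    p = EgmSimParams(n_fractionated=1, frac_amp_ratio=1.0,
                     frac_offset_ms_range=(70.0, 70.0),
                     deflection_width_ms=15.0, recovery_amp_ratio=0.0,
                     **_NOISE_FREE)
    return simulate_channel(p).samples[:, 0], p.fs


@pytest.fixture(scope="session")
def sharp_train():
    """Noise-free sharp periodic train (default 4 ms deflections, recovery lobe).

    Its spectrum has the fundamental at 5 Hz plus strong harmonics at
    10/15/20 Hz — the configuration the SPI penalizes.
    """
    p = EgmSimParams(n_fractionated=0, **_NOISE_FREE)
    return simulate_channel(p).samples[:, 0], p.fs


@pytest.fixture(scope="session")
def sine_5hz():
    """Pure 5 Hz unit sinusoid, 60 s at 1 kHz: single on-grid spectral line."""
    t = np.arange(60_000) / 1000.0
    return np.sin(2 * np.pi * 5.0 * t), 1000.0


@pytest.fixture(scope="session")
def regime_signals():
    """The 100-signal randomized suite spanning all generator regimes."""
    suite = regime_suite(n=100, seed=1)
    return [(p, simulate_channel(p).samples[:, 0]) for p in suite]
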
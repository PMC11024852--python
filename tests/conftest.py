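"""Shared fixtures: small synthetic traces and default configurations."""

from __future__ import annotations

import math

import numpy as np
import pytest

from difc import AnalysisConfig, Peak, SimulationConfig, simulate_scan


@pytest.fixture
def cfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def short_scan():
    """A 30-s in vivo scan at defaults with a handful of bright cells."""
    sim = SimulationConfig(duration_s=30.0, arrival_rate_per_min=20.0, seed=7)
    return simulate_scan(sim)


def make_peak(
    fiber: int = 1,
    apex_time_s: float = 1.0,
    amplitude: float = 10.0,
    width_s: float = 0.02,
    snr: float = 10.0,
) -> Peak:
    """Hand-built peak for matcher tests."""
    return Peak(
        fiber=fiber,
        apex_time_s=apex_time_s,
        amplitude=amplitude,
        width_s=width_s,
        snr=snr,
        start_time_s=apex_time_s - width_s,
        end_time_s=apex_time_s + width_s,
    )


def inject_gaussian(x: np.ndarray, rate: float, t0: float, amp: float,
                    fwhm_s: float) -> None:
    """Add a Gaussian transient to a raw series (test-side helper)."""
    sigma = fwhm_s / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    t = np.arange(x.size) / rate
    x += amp * np.exp(-0.5 * ((t - t0) / sigma) ** 2)
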
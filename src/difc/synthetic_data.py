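"""Synthetic two-probe DiFC traces with per-cell ground truth.

Real DiFC traces come off photomultiplier tubes attached to fiber probes on
a live mouse's tail (or on a flow phantom's tubing) and carry no ground
truth about which transient was a cell.  This module generates traces with
the statistical structure the analysis assumes, plus a complete event list,
so every stage of the chain is testable end to end:

* cell arrivals are a homogeneous Poisson process at a configurable rate
  (rare circulating cells: a few per minute);
* each cell deposits a Gaussian transient (default FWHM 20 ms, a plausible
  transit time through a probe's field of view) on fiber 1 at its arrival
  time and on fiber 2 after ``separation / speed`` seconds; amplitudes are
  log-normal per cell (brightness is multiplicative: label uptake x cell
  size x depth), highly but not perfectly correlated across fibers;
* the baseline is a constant background plus slow sinusoidal drift, with
  additive white Gaussian noise per sample;
* optional single-fiber artifacts emulate motion transients (off by
  default: the cell-free "PBS" analogue is then pure noise, mirroring the
  phantom's PBS control used to measure the false-alarm rate).

``phantom`` mode derives the flow speed from the pump rate and tubing bore
(plug flow: volumetric rate over cross-sectional area), matching a phantom
driven at 50 µL/min through microbore tubing.  Photon transport through the
phantom material is deliberately not modelled — the analysis operates
entirely in detector space — and the channel depth is metadata only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .trace_io import SimulationError, Trace

__all__ = [
    "SimulationConfig",
    "EventTruth",
    "DEFAULT_COHORT_DESIGN",
    "simulate_scan",
    "simulate_phantom",
    "phantom_speed_mm_s",
    "generate_cohort",
    "truth_to_frame",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one synthetic scan.

    Defaults emulate a 45-min in vivo scan sampled at 2 kHz with rare bright
    cells: the log-normal amplitude parameters put ~95% of cells above five
    times the default noise SD, reflecting labeled cells verified to be
    brighter than the detectability reference.  ``detect_floor_note``
    optionally records the expected fraction of cells below detectability;
    it is carried as provenance, not used by the generator.
    """

    mode: str = "in_vivo"                 # "in_vivo" | "phantom"
    duration_s: float = 2700.0
    rate_hz: float = 2000.0
    arrival_rate_per_min: float = 10.0
    amp_lognorm_mu: float = 2.45
    amp_lognorm_sigma: float = 0.5
    peak_fwhm_s: float = 0.020
    probe_separation_mm: float = 3.0
    speed_mm_s: float = 20.0
    flow_ul_min: float = 50.0             # phantom mode only
    tube_id_mm: float = 0.25              # phantom mode only
    noise_sd: float = 1.0
    background_level: float = 10.0
    drift_amplitude: float = 1.0
    drift_period_s: float = 60.0
    artifact_rate_per_min: float = 0.0
    amp_corr: float = 0.9                 # inter-fiber log-amplitude correlation
    amp_jitter: float = 0.05              # extra independent fiber-2 log jitter
    speed_jitter: float = 0.05            # per-cell fractional speed spread
    detect_floor_note: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        bad: list[str] = []
        if self.mode not in ("in_vivo", "phantom"):
            bad.append("mode (must be 'in_vivo' or 'phantom')")
        if not self.duration_s > 0:
            bad.append("duration_s (must be > 0)")
        if not self.rate_hz > 0:
            bad.append("rate_hz (must be > 0)")
        for key in ("arrival_rate_per_min", "artifact_rate_per_min", "noise_sd",
                    "amp_lognorm_sigma", "drift_amplitude", "amp_jitter",
                    "speed_jitter"):
            if getattr(self, key) < 0:
                bad.append(f"{key} (must be >= 0)")
        for key in ("peak_fwhm_s", "probe_separation_mm", "speed_mm_s",
                    "drift_period_s"):
            if not getattr(self, key) > 0:
                bad.append(f"{key} (must be > 0)")
        if not -1.0 <= self.amp_corr <= 1.0:
            bad.append("amp_corr (must be in [-1, 1])")
        if self.mode == "phantom":
            if not self.flow_ul_min > 0:
                bad.append("flow_ul_min (must be > 0 in phantom mode)")
            if not self.tube_id_mm > 0:
                bad.append("tube_id_mm (must be > 0 in phantom mode)")
        if bad:
            raise SimulationError("invalid simulation config: " + "; ".join(bad))


@dataclass(frozen=True)
class EventTruth:
    """Ground truth for one injected event (cell transit or artifact).

    For cells, ``t_fiber2_s - t_fiber1_s == probe_separation / speed``.
    Artifacts appear on exactly one fiber; the absent fiber's time and
    amplitude are NaN, as is the speed.
    """

    event_id: int
    kind: str  # "cell" | "artifact"
    t_fiber1_s: float
    t_fiber2_s: float
    amp_fiber1: float
    amp_fiber2: float
    speed_mm_s: float


def phantom_speed_mm_s(flow_ul_min: float, tube_id_mm: float) -> float:
    """Plug-flow speed in tubing: volumetric rate over cross-section.

    1 µL = 1 mm^3, so speed [mm/s] = (Q/60) / (pi (d/2)^2).  At 50 µL/min
    through 0.25 mm ID tubing this is ~17 mm/s.
    """
    if flow_ul_min <= 0 or tube_id_mm <= 0:
        raise SimulationError("flow rate and tube inner diameter must be positive")
    area_mm2 = math.pi * (tube_id_mm / 2.0) ** 2
    return (flow_ul_min / 60.0) / area_mm2


def _inject_gaussian(
    series: np.ndarray, rate: float, t0: float, amplitude: float, fwhm_s: float
) -> None:
    """Add a Gaussian transient in place, truncated at +/- 5 sigma."""
    sigma = fwhm_s * _FWHM_TO_SIGMA
    lo = max(0, int(math.floor((t0 - 5 * sigma) * rate)))
    hi = min(series.size, int(math.ceil((t0 + 5 * sigma) * rate)) + 1)
    if hi <= lo:
        return
    t = np.arange(lo, hi) / rate
    series[lo:hi] += amplitude * np.exp(-0.5 * ((t - t0) / sigma) ** 2)


def _simulate(cfg: SimulationConfig, speed_mm_s: float) -> tuple[Trace, list[EventTruth]]:
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.rate_hz))
    t = np.arange(n) / cfg.rate_hz

    # Baseline: constant background + slow sinusoidal drift (seeded phase).
    phase = rng.uniform(0, 2 * math.pi)
    baseline = cfg.background_level + cfg.drift_amplitude * np.sin(
        2 * math.pi * t / cfg.drift_period_s + phase
    )
    ch1 = baseline.copy()
    ch2 = baseline.copy()

    truth: list[EventTruth] = []

    # Cell transits: homogeneous Poisson arrivals over the scan.
    n_cells = rng.poisson(cfg.arrival_rate_per_min * cfg.duration_s / 60.0)
    arrivals = np.sort(rng.uniform(0.0, cfg.duration_s, size=n_cells))
    z1 = rng.standard_normal(n_cells)
    z2 = rng.standard_normal(n_cells)
    z3 = rng.standard_normal(n_cells)
    log_a1 = cfg.amp_lognorm_mu + cfg.amp_lognorm_sigma * z1
    log_a2 = (
        cfg.amp_lognorm_mu
        + cfg.amp_lognorm_sigma
        * (cfg.amp_corr * z1 + math.sqrt(1.0 - cfg.amp_corr**2) * z2)
        + cfg.amp_jitter * z3
    )
    speeds = speed_mm_s * (1.0 + cfg.speed_jitter * rng.standard_normal(n_cells))
    speeds = np.clip(speeds, 0.05 * speed_mm_s, None)  # no stalled/reversed cells

    for k in range(n_cells):
        t1 = float(arrivals[k])
        delay = cfg.probe_separation_mm / float(speeds[k])
        t2 = t1 + delay
        a1, a2 = float(np.exp(log_a1[k])), float(np.exp(log_a2[k]))
        _inject_gaussian(ch1, cfg.rate_hz, t1, a1, cfg.peak_fwhm_s)
        _inject_gaussian(ch2, cfg.rate_hz, t2, a2, cfg.peak_fwhm_s)
        truth.append(
            EventTruth(
                event_id=k, kind="cell", t_fiber1_s=t1, t_fiber2_s=t2,
                amp_fiber1=a1, amp_fiber2=a2, speed_mm_s=float(speeds[k]),
            )
        )

    # Single-fiber motion/instrument artifacts: broader amplitude and width
    # distributions, one fiber each.
    n_art = rng.poisson(cfg.artifact_rate_per_min * cfg.duration_s / 60.0)
    art_times = np.sort(rng.uniform(0.0, cfg.duration_s, size=n_art))
    for k in range(n_art):
        fiber = int(rng.integers(1, 3))
        amp = float(rng.lognormal(cfg.amp_lognorm_mu, 2.0 * cfg.amp_lognorm_sigma))
        fwhm = float(cfg.peak_fwhm_s * rng.lognormal(math.log(3.0), 0.6))
        t0 = float(art_times[k])
        _inject_gaussian(ch1 if fiber == 1 else ch2, cfg.rate_hz, t0, amp, fwhm)
        truth.append(
            EventTruth(
                event_id=n_cells + k, kind="artifact",
                t_fiber1_s=t0 if fiber == 1 else float("nan"),
                t_fiber2_s=t0 if fiber == 2 else float("nan"),
                amp_fiber1=amp if fiber == 1 else float("nan"),
                amp_fiber2=amp if fiber == 2 else float("nan"),
                speed_mm_s=float("nan"),
            )
        )

    if cfg.noise_sd > 0:
        ch1 += rng.normal(0.0, cfg.noise_sd, size=n)
        ch2 += rng.normal(0.0, cfg.noise_sd, size=n)

    truth.sort(key=lambda e: np.nanmin([e.t_fiber1_s, e.t_fiber2_s]))
    trace = Trace(
        scan_id=f"sim_{cfg.mode}_{cfg.seed}",
        sampling_rate_hz=cfg.rate_hz,
        channels=(ch1, ch2),
        meta={"mode": cfg.mode, "sim_seed": str(cfg.seed)},
    )
    return trace, truth


def simulate_scan(cfg: SimulationConfig) -> tuple[Trace, list[EventTruth]]:
    """Generate one two-probe scan and its complete, sorted truth list.

    Identical config (including seed) yields identical traces and truth.
    In phantom mode the flow speed is derived from the pump rate and tubing
    bore; in vivo mode uses ``cfg.speed_mm_s`` directly.
    """
    if cfg.mode == "phantom":
        return simulate_phantom(cfg)
    return _simulate(cfg, cfg.speed_mm_s)


def simulate_phantom(cfg: SimulationConfig) -> tuple[Trace, list[EventTruth]]:
    """Generate a flow-phantom scan: speed = Q / (pi r^2), then the common model.

    A cell-free PBS control is the same config with ``arrival_rate_per_min``
    set to 0.
    """
    if cfg.mode != "phantom":
        cfg = replace(cfg, mode="phantom")
    return _simulate(cfg, phantom_speed_mm_s(cfg.flow_ul_min, cfg.tube_id_mm))


# (condition, timepoint, n_mice, arrival_rate_per_min).  Rates are synthetic
# stand-ins shaped like the studied biology: circulating labeled macrophage
# numbers maximal at 12 h post clodronate, lower at 6 h and 24 h, and
# near-zero in PBS and no-clodronate controls.
DEFAULT_COHORT_DESIGN: tuple[tuple[str, str, int, float], ...] = (
    ("clodronate", "6 h", 4, 4.0),
    ("clodronate", "12 h", 4, 10.0),
    ("clodronate", "24 h", 4, 6.0),
    ("no_clodronate", "12 h", 4, 0.0),
    ("pbs", "12 h", 4, 0.0),
)


def generate_cohort(
    design: Sequence[tuple[str, str, int, float]] = DEFAULT_COHORT_DESIGN,
    base_cfg: SimulationConfig | None = None,
    seed: int = 0,
    replicates_per_mouse: int = 4,
) -> list[tuple[Trace, list[EventTruth]]]:
    """Simulate a labeled cohort: one seeded scan per mouse per replicate.

    ``design`` rows are (condition, timepoint, n_mice, arrival_rate_per_min);
    each scan's trace carries condition/timepoint/subject labels in its
    metadata so they flow through to scan summaries and group tables.  The
    default design and 4 replicates per mouse emulate a longitudinal
    depletion study scanned in quadruplicate.
    """
    if not design:
        raise SimulationError("cohort design must be nonempty")
    if replicates_per_mouse < 1:
        raise SimulationError("replicates_per_mouse must be >= 1")
    base_cfg = base_cfg or SimulationConfig()
    seeder = np.random.default_rng(seed)
    out: list[tuple[Trace, list[EventTruth]]] = []
    for condition, timepoint, n_mice, rate in design:
        for mouse in range(1, n_mice + 1):
            for rep in range(1, replicates_per_mouse + 1):
                scan_seed = int(seeder.integers(0, 2**31 - 1))
                cfg = replace(
                    base_cfg, arrival_rate_per_min=float(rate), seed=scan_seed
                )
                trace, truth = simulate_scan(cfg)
                label = timepoint.replace(" ", "")
                trace.scan_id = f"{condition}_{label}_m{mouse}_r{rep}"
                trace.meta.update(
                    condition=condition,
                    timepoint=timepoint,
                    subject=f"{condition}_{label}_m{mouse}",
                )
                out.append((trace, truth))
    return out


def truth_to_frame(truth: list[EventTruth]) -> pd.DataFrame:
    """Ground-truth events as a table (one row per event)."""
    return pd.DataFrame([e.__dict__ for e in truth])
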
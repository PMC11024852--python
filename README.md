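# difc — two-probe diffuse in vivo flow cytometry trace analysis

Diffuse in vivo flow cytometry (DiFC) counts rare fluorescently labeled
cells in circulation without drawing blood: two optical fiber probes rest on
the skin over a blood vessel (or on a tissue-mimicking flow phantom), and
each labeled cell transiting a probe's field of view produces a transient
fluorescence spike on that probe's photomultiplier trace.  Typical use is
enumeration of circulating tumor cells or, as here, rare circulating immune
cells such as labeled peritoneal macrophages, over 45-minute scans at counts
of a few cells per minute.

This package implements the full analysis chain for such traces, plus a
ground-truth simulator so every stage is verifiable without instrument data.
It is aimed at researchers analyzing two-channel DiFC recordings or
prototyping detection/matching parameters in simulation.

## Method

For each fiber channel with raw intensity `y(t)` sampled at rate `f_s`:

1. **Background subtraction** — a moving-median baseline `b(t)` over a
   window (default 2.5 s) much longer than a cell transit removes slow
   drift; the residual is `r(t) = y(t) − b(t)`.
2. **Smoothing** — a moving average (default 5 ms) much shorter than the
   ~20 ms transit time suppresses sample noise.
3. **Noise estimation** — one noise value per channel per scan,
   `σ = SD(r)` (a robust MAD-based estimator is available).
4. **Peak detection** — maximal runs with `r(t) ≥ k·σ` are *peaks*, with
   threshold factor `k = 5` by default; runs closer than 10 ms merge, and
   runs with FWHM below 5 ms are discarded as electronic spikes.  Each peak
   carries apex time, amplitude (apex of `r`), FWHM, and `SNR = amplitude/σ`.
5. **Cross-probe matching** — a cell in flow appears on both probes with
   similar height and width, separated by the travel time between probes.
   Candidate pairs within a delay window (default 0.5 s) whose amplitude
   and width ratios are within a factor of 2 are scored by
   `|ln(a₁/a₂)| + |ln(w₁/w₂)| + |Δt|/window` and accepted greedily in
   ascending score.  The delay sign gives the flow direction (arterial vs
   venous); `speed = separation / |Δt|`.
6. **Quantification** — per scan, the count rate (peaks/min) and mean peak
   amplitude on the *primary fiber* (by default the fiber with more peaks,
   matching the convention of reporting the probe with the most detections);
   per cohort, mean ± SEM tables by condition and timepoint.  A false-alarm
   rate measured on cell-free controls (a PBS suspension in the phantom) is
   reported separately and can optionally be subtracted.

The simulator generates both-probe traces with Poisson cell arrivals,
log-normal per-cell brightness correlated across fibers, Gaussian transit
peaks, baseline drift, white noise, and optional single-probe motion
artifacts.  Phantom mode derives the flow speed from the pump rate and
tubing bore via plug flow, `v = Q / (π r²)` — at 50 µL/min through 0.25 mm
ID tubing, ≈ 17 mm/s.  Every simulated scan comes with a complete per-cell
truth table.

## Worked example

```python
from difc import (AnalysisConfig, SimulationConfig, analyze_trace,
                  estimate_speed, simulate_phantom)
import numpy as np

# Flow-phantom scan: labeled cells pumped at 50 uL/min through 0.25 mm
# tubing, 5 cells/min on average, 10-min scan sampled at 2 kHz.
sim = SimulationConfig(mode="phantom", duration_s=600.0,
                       arrival_rate_per_min=5.0, seed=42)
trace, truth = simulate_phantom(sim)

peaks1, peaks2, matches, summary = analyze_trace(trace, AnalysisConfig())
speeds = [estimate_speed(m, sim.probe_separation_mm) for m in matches]

print(f"true cells simulated      : {sum(e.kind == 'cell' for e in truth)}")
print(f"peaks on primary fiber    : {summary.peak_count}")
print(f"count rate                : {summary.count_rate_per_min:.2f} cells/min")
print(f"mean peak amplitude       : {summary.mean_peak_amplitude:.2f} a.u.")
print(f"matched fraction          : {summary.matched_fraction:.2f}")
print(f"median recovered speed    : {np.median(speeds):.1f} mm/s")
```

Output:

```
true cells simulated      : 49
peaks on primary fiber    : 49
count rate                : 4.90 cells/min
mean peak amplitude       : 11.30 a.u.
matched fraction          : 1.00
median recovered speed    : 16.8 mm/s
```

All 49 simulated cells were detected at the 5×-noise criterion and matched
across the probes; the recovered speed agrees with the plug-flow value of
17.0 mm/s for this pump rate and bore.

## Command-line pipeline

Stages communicate through plain text files and each writes a JSON
provenance manifest:

```sh
difc simulate --out runs/traces --cohort --seed 1         # traces + truth
difc detect runs/traces/*.tsv --out runs/peaks            # peak tables
difc match runs/peaks/*.peaks.tsv --out runs/matches      # matched pairs
difc summarize runs/peaks/*.peaks.tsv --match-dir runs/matches \
    --out runs/summary                                    # scan + group tables
difc all --out runs/full --seed 1                         # everything
```

Trace files are `#`-headed delimited text (`time_s`, `fiber1`, `fiber2`);
analysis parameters load from TOML (`difc detect --config analysis.toml ...`).

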
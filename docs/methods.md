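# Methods

This note documents the signal model, the analysis chain and its defaults,
what the simulator does and does not emulate, the numerical choices, and
known limitations.

## Signal model and assumptions

A DiFC scan yields two synchronized photomultiplier intensity series, one
per fiber probe, in arbitrary detector units.  The analysis assumes:

* rare, sparse transients: cells transit a probe's field of view in tens of
  milliseconds and occupy a negligible fraction of the scan;
* a slowly varying baseline (probe coupling, ambient light, physiology)
  changing on timescales ≫ one transit;
* approximately stationary, approximately Gaussian additive noise within a
  scan, summarized by a single standard deviation per channel;
* a cell seen by both probes produces transients of similar height and
  width, separated by the inter-probe travel time; motion and instrument
  artifacts are predominantly single-probe events.

Coincident arrivals are reported as one peak (no deconvolution), and no
spectral unmixing is attempted.

## Analysis chain

Order of operations per channel: background subtraction → smoothing → noise
estimation on the smoothed residual → thresholding.  Smoothing before
detection is standard matched-filter logic — averaging at a fraction of the
transit time maximizes SNR — and the noise entering the threshold is the
noise of the same series that is thresholded, so peak SNR values are
internally consistent.  The preprocessed channel stores the detection-ready
residual and defines background as raw − residual, so the two always
reconstruct the raw series exactly; with smoothing enabled the background
therefore also carries the removed high-frequency component.

### Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `threshold_factor` | 5 | — | the DiFC detection criterion: spikes at least five times the noise SD |
| `background_window_s` | 2.5 | s | ≫ transit FWHM (~20 ms), ≪ drift period; the median ignores sparse transients |
| `smoothing_window_s` | 0.005 | s | ≪ transit FWHM, suppresses per-sample noise |
| `min_peak_width_s` | 0.005 | s | rejects single-sample electronic spikes |
| `merge_gap_s` | 0.010 | s | fuses threshold runs split by noise dips within one transit |
| `match_delay_window_s` | 0.5 | s | travel time over 3 mm at tail-vessel speeds ≥ 5 mm/s, with headroom |
| `amplitude_ratio_tol`, `width_ratio_tol` | 2 | — | "similar peaks" implemented as height and width within a factor of 2 |
| `noise_method` | `plain_sd` | — | the literal noise definition (SD of the data); `robust` (scaled MAD) offered because sparse tall peaks inflate the plain SD, which lowers sensitivity but never validity |
| `primary_fiber_rule` | `most_peaks` | — | report the fiber with the most detections (tie → fiber 1) |

Noise is estimated once per channel per scan (a single SD), matching the
single-noise-value convention; rolling noise estimation is deliberately not
the default.

### Matching

Candidates are cross-probe pairs within the delay window passing both ratio
gates; the score `|ln(a₁/a₂)| + |ln(w₁/w₂)| + |Δt|/window` is symmetric in
the fibers up to sign.  Pairs are accepted greedily in ascending score
(ties broken by earlier fiber-1 apex).  Greedy assignment is exactly
optimal whenever the candidate graph decomposes into stars — the rare-event
regime, inter-arrival ≫ delay window, which these scans inhabit — and
measured to differ from the exhaustive minimum-score matching in well under
1% of deliberately dense instances (two true pairs inside one window).
Both delay signs are matched; direction is reported, never filtered, since
cells are counted in both arterial and venous flow.

Matched fractions can be low on real instruments (small probe
misalignments); the fraction is therefore reported alongside the primary-
fiber counts rather than used to reject peaks.

## Simulator

`simulate_scan` emulates: homogeneous Poisson cell arrivals; Gaussian
transit peaks (default FWHM 20 ms) deposited on fiber 1 at arrival and on
fiber 2 after `separation/speed`; per-cell log-normal amplitudes
(brightness is multiplicative in label uptake, cell size and depth) with
inter-fiber log-correlation 0.9 plus 5% independent jitter, so matching
gates are exercised but not trivially satisfied; per-cell speed jitter of
5% (plug flow, no parabolic profile); a constant background with sinusoidal
drift; white Gaussian noise; and optional single-fiber artifacts with
broader amplitude/width distributions.  Defaults are a 45-min scan (2700 s)
at 2 kHz — the sampling rate is a package choice carried in the trace
header, since detector-specific acquisition rates vary — with amplitude
parameters (µ = 2.45, σ = 0.5 in log space, unit noise SD) placing ~95% of
cells above the 5×-noise floor, reflecting labeled cells verified brighter
than a reference microsphere.

Phantom mode derives speed from the pump rate and tubing bore,
`v = (Q/60)/(π(d/2)²)` with Q in µL/min and d in mm: 50 µL/min through
0.25 mm ID microbore tubing gives 16.98 mm/s.  The 0.25 mm bore is a
typical microbore value and is configuration, not a constant.  Photon
diffusion through the phantom material is *not* modelled — the analysis
operates entirely in detector space — and the channel depth is metadata
only.  A cell-free "PBS" run is the same configuration with arrival rate 0;
since artifacts default to 0/min, that is a pure-noise trace, the analogue
of the PBS control used to measure the false-alarm rate.

`generate_cohort` ships a default longitudinal design shaped like a
depletion time-course: arrival rates {4, 10, 6} cells/min at the 6 h, 12 h
and 24 h labels (maximum at 12 h) and 0 for PBS and no-treatment controls,
4 mice per group scanned in quadruplicate.  The rates are synthetic
stand-ins chosen at realistic rare-cell magnitudes; only their ordering is
treated as meaningful.

**What the simulator does not emulate** — and hence what passing tests do
not establish about real data: non-Gaussian or non-stationary detector
noise, probe decoupling events, parabolic flow profiles (transit-time
dispersion), overlapping-cell waveform shapes, depth-dependent optical
attenuation, and any pharmacokinetics linking biology to arrival rates.

## Numerical choices

* Moving median background: exact (pandas rolling) for windows ≤ 512
  samples; for larger windows the median is evaluated every half-window and
  linearly interpolated.  The baseline is constrained to vary on the window
  scale, so the interpolation error is negligible (measured ≤ 0.035 units
  against the exact median on unit-noise drifting traces, vs a detection
  threshold of 5).  Even windows are widened by one sample for symmetry;
  edges are reflection-padded.
* Smoothing uses mirror (reflection) padding; a sub-sample window is the
  identity.
* FWHM is measured by linear interpolation at the half-apex crossings,
  searching outward from the apex (geometrically widening windows keep the
  cost local); a peak at the trace edge clips to the edge.
* Threshold runs use `residual ≥ k·σ` (closed at the threshold); zero noise
  with a non-zero residual is an error (no threshold can be formed), while
  an identically zero residual yields no peaks.
* Greedy matching sorts candidates by (score, fiber-1 apex, fiber-2 apex),
  making results deterministic.
* SEM is sample SD (ddof = 1) over √n; single-scan groups report SEM as
  undefined (NaN), and per-scan undefined values (mean amplitude of a
  peakless scan) are excluded from group aggregation.
* Simulation determinism: (config, seed) fully determines traces and truth;
  cohort scans draw child seeds from a single seeded generator.

## Validation design and problem sizes

The test suite validates each stage against an independent reference:
brute-force moving-median and moving-mean oracles, a sample-by-sample
detection scan, exhaustive matching enumeration, Poisson closed forms, and
the plug-flow formula.  End-to-end checks run the full pipeline on
simulated scans with truth tables.

Sizes were chosen to keep the default suite and the acceptance script at a
few minutes on one CPU while leaving the statistics decisive:

* threshold recovery: 30-s unit-noise traces, three replicate bisections of
  32 trials each.  Smoothing is set to the transit FWHM (20 ms) for this
  measurement: a matched filter concentrates detection into effectively one
  noise draw.  With that configuration the measured 50%-detection point
  sits ~5–8% below `threshold_factor × σ` — the residual bias of any
  "50% detected" limit, since the local noise maximum helps detection more
  often than it hurts — which is within the ±10% validation band; with the
  5-ms default the bias would be ~20%.
* detector-oracle equivalence: 200 traces of 10⁴–3×10⁴ samples, exact
  agreement of counts and apex indices.
* Poisson recovery: full 45-min scans at 2 kHz, rates {1, 5, 10, 35}/min,
  bright cells (SNR ≥ 10), 20 seeds per rate in the suite (10 in the
  script), requiring ≥ 95% of runs within 3 Poisson SE.
* false-alarm floor: twenty 45-min cell-free scans at defaults
  (mean ≤ 0.2 peaks/min; measured ≈ 0.02).
* matching fidelity: ten 2-min bright scans (precision/recall ≥ 0.9) and
  six phantom scans for delay/speed recovery within 10%.
* cohort recovery: 100 end-to-end runs (50 in the script) of the shipped
  design at 300-s scans, 500 Hz, one replicate per mouse — the ordering
  statistic is invariant to scan length; only Poisson error widens, and at
  these sizes an ordering violation has probability ≪ 5%.

## Known limitations

* The greedy matcher is not globally optimal on dense candidate graphs;
  at arrival rates where inter-arrival times approach the delay window,
  matched fractions and pairing accuracy degrade before count rates do.
* A single per-scan noise SD underestimates sensitivity drift within a
  scan; segmented noise estimation would be needed for strongly
  non-stationary recordings.
* Plain-SD noise estimation is inflated by high event rates (≈ √(1+ρ)
  with ρ the signal-to-noise power ratio of the trace), lowering
  sensitivity at high counts; the robust estimator avoids this at the cost
  of departing from the literal SD definition.
* Amplitudes are reported in detector units; no absolute calibration to
  cell brightness is attempted.
* The edge half-window of the background estimator relies on reflection
  padding; peaks within one background window of the scan edges have
  slightly biased baselines.
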
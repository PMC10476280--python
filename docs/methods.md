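# Methods

This document specifies the models, defaults, and numerical choices behind
each stage of the pipeline, and the limitations that follow from them. All
quantitative behavior claimed here is exercised by the test suite
(`tests/`) or the acceptance script (`scripts/acceptance.py`); nothing below
rests on unverified assertions.

## Acquisition schedule

`AcquisitionSchedule(total_duration, channel_intervals)` defines a uniform
frame grid per channel starting at t = 0 and including the final frame at
`total_duration` when it lands on the grid. The default — 2,700 s with DNA
(647) frames every 60 s and protein (488/561) frames every 5 s — yields 46
DNA frames and 541 protein frames. All pulse times and durations live on
this grid.

## Stochastic binding simulator

Each spot × protein channel evolves as an independent continuous-time
two-state chain:

- OFF → ON at rate `k_on` (arrivals).
- ON → OFF at rate `k_off + k_bleach`; the cause of each loss event is drawn
  proportionally to the component rates (competing exponential risks). The
  simulator therefore obeys two identities used as acceptance checks: the
  observed total loss rate equals `k_off + k_bleach`, and the fraction of
  bleach-caused losses equals `k_bleach / (k_off + k_bleach)`.

Rates are in events/hour. Sampling is event-driven (exact, Gillespie-style)
in continuous time; the frame raster merely observes the chain, so dwell
times are not quantized at generation. Intervals still in progress at the
end of acquisition are recorded with cause `end_of_acquisition`.
`initial_occupancy` sets the probability that a spot starts ON (stationary
snapshots, endpoint mode).

Spot centroids are placed by random sequential adsorption with a minimum
separation (default 8 px) and an edge margin (default 12 px); the field is
rejected up-front if the requested density is beyond what dart-throwing can
reliably reach (n·sep² > 0.35 × usable area).

### Rendering

Each bound molecule paints an integrated-intensity Gaussian PSF
(`spot_amplitude` photons total, default 800; `psf_sigma` 1.3 px) onto a
constant background (default 200 photons), displaced by the programmed drift
(linear velocity plus optional sinusoidal wobble), then Poisson noise is
applied (Gaussian and noise-free models available for controlled tests). The
DNA channel renders every template in every frame.

With the defaults, the peak pixel is `amplitude / (2π σ²) ≈ 75` photons over
background, i.e. peak SNR ≈ 5 against Poisson noise — deliberately
realistic for single-fluorophore TIRF. Aperture-averaged trace SNR is much
higher (~10 per frame), so time-lapse detection is robust while single-frame
detection is marginal (see Limitations).

### Realism limits

The simulator omits several properties of real data: fluorophore blinking,
nonuniform illumination and vignetting, camera read noise/EM gain statistics,
chromatic offset between channels, axial drift/defocus, spot-to-spot
brightness heterogeneity, and nonspecific surface binding. Drift is smooth
and global; real stages also jitter. These omissions mean pipeline
performance numbers measured here are upper bounds on real-data performance.

## Image pipeline

- **Drift estimation** (DNA channel): per-frame phase cross-correlation
  against frame 0 (scikit-image, upsample factor 50), negated to convert
  reported shift into content displacement; or a linear least-squares
  translation fit over time. `auto` uses phase correlation and switches to
  the linear fit beyond 5 px cumulative drift. Correction resamples frames
  by bilinear interpolation (`scipy.ndimage.shift`). Verified: programmed
  10.8 px cumulative drift recovered with < 0.25 px error and < 0.25 px
  residual after correction.
- **Spot detection** (DNA channel): global threshold = median + 4×MAD of
  pooled raw frame pixels (robust to sparse bright spots; pooling raw frames
  rather than a temporal-median image keeps the threshold calibrated to
  per-frame noise), connected components with area in [2, 30] px,
  background-subtracted intensity-weighted centroids, per-frame detections
  linked within 2 px, and tracks present in < 50% of frames discarded
  (transient artifacts). Single-frame stacks skip the persistency vote
  (endpoint mode).
- **Trace extraction**: raw = mean over a 3 px disc at the spot centroid;
  background = median over a 5–8 px annulus excluding other spots'
  apertures; z = (raw − background − center)/scale, where center and scale
  are the median and 1.4826×MAD of the series after one-sided sigma clipping
  (frames above center + 3×scale iteratively excluded, stopping if fewer
  than max(8, 25%) of frames would remain). The scale is floored by a noise
  estimate from first differences between consecutive baseline frames. The
  clipping keeps baselines honest up to ~50% ON duty cycle; the z-score is
  invariant to affine rescaling of intensities, and a constant trace maps to
  z = 0. Spots whose annulus leaves the field are flagged invalid and
  excluded.

## Pulse detection

A frame is ON iff z ≥ `z_threshold` (default 3.0; non-finite frames are OFF
with a warning). Maximal ON runs are extracted; OFF gaps of at most
`max_gap_frames` (default 0) are bridged first (bridged frames count toward
duration), then runs shorter than `min_on_frames` (default 2) are
discarded. Duration = ON-frame count × frame interval, so a single detected
frame represents one full interval and durations sit on the acquisition
grid. Runs touching the final frame are right-censored; runs touching the
first frame are flagged present-at-start but not additionally censored
(their full extent is unknown on the left, not the right). The
implementation is verified exactly against an independent brute-force
run-length oracle on 10,000 random series, including flags.

Defaults rationale: `min_on_frames = 2` suppresses single-frame noise
excursions at the cost of a 2-frame (10 s) detection floor;
`max_gap_frames = 0` avoids conflating blinking with re-binding — users with
blinking fluorophores should raise it deliberately.

### Photobleach step counting

Piecewise-constant fit by penalized recursive binary segmentation (split
kept while it reduces SSE by more than `3 σ² log n`, with σ estimated from
temporal first differences), then segment-to-segment decreases of at least
20% of the initial above-baseline amplitude are counted as steps; upward
jumps reset the reference level. Verified: exact on noise-free staircases,
zero on flat noise, and ≥ 70% correct (modal count = 2) on 200 simulated
two-dye staircases at SNR 5 — near-simultaneous bleach events within a
segment-resolution window merge, which is the dominant error mode.

## Residence partitioning

For each focal pulse, partner co-residency on the same spot divides its
duration into five classes: T1 (partner already resident at focal arrival,
time fully ternary), T2 (co-arrival within ±5 s, inclusive, fully ternary),
T3 (time before the partner's arrival, non-ternary), T4 (partner never
co-resident, non-ternary), T5 (ternary time after a partner arrival,
carried forward). T1+T2+T5 is ternary time, T3+T4 non-ternary; their sum
equals the focal duration exactly (conservation verified on 10,000 random
configurations). A detachment event is assigned to the ternary pool iff the
residence was ever ternary. Overlapping partner pulses are merged by
interval union; overlapping focal pulses at one spot are rejected as a data
error. Derived summaries: occupancy fraction (ternary overlap over duration
among ever-ternary residences), arrival-class proportions, and mean
residences per spot.

## Survival and rate statistics

- **Off-rate**: `k = N_off / ΣT` (per hour) — the exponential MLE under
  right censoring; censored residences contribute time but no event.
  Verified to recover programmed rates within 3 s.d. (`k/√N`) with < 0.4%
  relative bias at n = 5,000×20.
- **Kaplan–Meier**: via `lifelines`, exponential-Greenwood log-log
  confidence band; the reported median is the step-function median (first
  time S ≤ 0.5), undefined if the curve never reaches 0.5 (reported as
  such, never extrapolated). Verified against hand-computed censored
  examples and exact equality with empirical survival in the uncensored
  case.
- **Log-rank test**: via `lifelines.statistics`; verified against a
  hand-enumerated hypergeometric risk-set calculation and calibrated to
  type-I error 0.05 ± 0.015 over 2,000 null replicates.
- **Rate comparison across replicates**: two-tailed unpaired equal-variance
  t-test (scipy) on replicate-level rates; degenerate zero-variance inputs
  are handled explicitly (p = 1 for equal means, p = 0 with a warning
  otherwise).
- **Duration summaries**: fractions of residences strictly below 120 s and
  strictly above 300 s; verified against closed-form exponential tail
  probabilities.
- **Photobleach controls**: bleach-only dwell pools summarized by KM; the
  median lands within the confidence band of `ln(2)/k_bleach`.

## Reproducibility

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`/`SeedSequence`; sub-streams (noise, per-field
seeds) are derived, never shared. A fixed config + seed reproduces every
output file byte-for-byte (tested). `manifest.json` embeds the package
version and the full config; statistics are recomputable from `pulses.csv`
alone and match the image-path run exactly (tested).

## Limitations

- **Single-frame (endpoint) detection is SNR-limited**: at the default
  rendering parameters (~5 peak-pixel SNR), one frame misses ~10–15% of
  true spots, biasing snapshot colocalization low. Endpoint experiments need
  brighter labels, longer effective exposure, or frame averaging; the
  endpoint tests use bright spots to isolate the colocalization logic.
- **Baseline estimation fails above ~50% ON duty cycle**: sigma clipping
  cannot recover a baseline that is the minority level, so traces from
  near-saturated spots lose events (the clipping floor keeps ≥ 25% of
  frames). Rates from such regimes are biased; the simulator's defaults
  (duty cycle ≲ 10%) are far from this regime, but dense real data may not
  be.
- **Frame quantization**: durations are multiples of the frame interval;
  dwells shorter than `min_on_frames` intervals are invisible, and measured
  distributions are discretized versions of the underlying continuous ones.
  For exponential dwells the rate estimator is insensitive to the left
  truncation (memorylessness) but not to the discretization at very fast
  rates (mean dwell approaching the frame interval).
- **Bleaching is not subtracted, only bounded**: reported off-rates from
  labeled-protein pulses are total loss rates; separating `k_off` from
  `k_bleach` requires the bleach-only control experiment.
- **Co-arrival window (±5 s, one protein frame)** is a convention; ternary
  classification near the window boundary is sensitive to it.
- **Drift model**: estimation assumes global translation; rotation,
  magnification drift, or local deformation are not modeled or corrected.
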
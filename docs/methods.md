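# Methods

## The closed-loop model

The simulated loop reproduces the timing structure of a real phase-locked
stimulation rig. A sample recorded at time `s` becomes visible to the
controller at `s + acquisition + buffer` (data arrive in buffer-sized
blocks; defaults: acquisition 0 ms, buffer 10 ms). The controller wakes
once per buffer hop. At a wake at wall time `t` it:

1. takes the newest causally coverable time point, `t_c = t - acquisition -
   buffer - L/2`, where `L` is the Morlet kernel length — the kernel group
   delay `L/2` is an *estimation lag* distinct from, and added to, the
   hardware budget;
2. reads phase and amplitude from the wavelet coefficient centered at
   `t_c`, and instantaneous frequency from the least-squares slope of the
   unwrapped coefficient phase over the preceding 25 ms;
3. predicts the phase a pulse commanded now would arrive at:
   `phi_hat = wrap(phi + 2*pi*f*(t + compute + transport + rise - t_c))`;
4. computes the wait until the predicted phase crosses the target,
   `wait = wrap_{[0,2pi)}(target - phi_hat) / (2*pi*f)`, quantized to the
   sample grid. If the crossing falls before the next wake, the amplitude
   gate passes, the residual error is within the phase tolerance, and the
   refractory period has elapsed, the command is scheduled at
   `t + compute + wait` and delivered `transport + rise` later.

Step 4 is the one place the design was genuinely open. A rule that fires
exactly at hop boundaries whenever the predicted phase lies within the
tolerance band cannot hit arbitrary phases at 20 Hz — a 10 ms hop advances
a 20 Hz rhythm by 1.26 rad, far coarser than the 0.3 rad tolerance — and
when the hop grid is phase-locked to the rhythm it systematically samples
the leading edge of the band (a ~0.14 rad bias in our 4 Hz tests).
Scheduling the command *within* the upcoming hop, as hardware TTL queues
do, removes both artifacts while remaining strictly causal: the wait is
computed from the current estimate only.

Implementation note: the wavelet coefficients for a whole record are
computed with one overlap-add convolution, and the loop only ever indexes
coefficients whose kernel support lies inside the causally available data.
This is arithmetically identical to the per-hop windowed dot product (a
test asserts the equivalence) and far faster.

## Phase estimation

The kernel is a Gaussian-windowed complex exponential with temporal SD
`sigma_t = n_cycles / (2*pi*f0)`, truncated at `n_cycles / f0` seconds
(~±3.1 SD), discretely admissibility-corrected to sum to zero, and
L2-normalized. Phase uses the cosine convention: 0 rad = oscillation peak,
pi rad = trough. Defaults: `n_cycles = 4` at 4 Hz (kernel 1 s, group delay
0.5 s) and `7` at 20 Hz (kernel 0.35 s) — a compromise between frequency
selectivity and causal lag. Near-zero band amplitude yields an estimate
flagged undefined; the controller treats it as "do not fire".

Instantaneous frequency is clamped to the band's passband — (3, 8) Hz for
the 4 Hz band, (16, 25) Hz for the 20 Hz band. The low edge of the 4 Hz
passband sits below the band center because the synthetic oscillator's
frequency walk is reflected at ±2 Hz around 4 Hz; a filter starting at
4 Hz would sit on top of the rhythm it is meant to isolate.

The offline scoring oracle is the standard acausal reference: 4th-order
Butterworth band-pass applied forward-backward (zero phase), then the
analytic-signal angle, interpolated at pulse delivery times.

## Synthetic data

The generators encode the study conditions under which everything is
tested; all are deterministic given a seed.

- **LFP**: each oscillator is a phase-continuous sinusoid whose
  instantaneous frequency performs a Gaussian random walk (SD
  `frequency_jitter_sd` per √s) reflected at `±max_frequency_deviation`
  (default ±2 Hz at 4 Hz, ±4 Hz at 20 Hz), plus `1/f^exponent` Gaussian
  noise scaled to a target SD. Defaults for closed-loop experiments:
  oscillator amplitude 1, noise SD 0.5 (amplitude-SNR 2), jitter
  0.3 Hz/√s at 4 Hz and 0.5 at 20 Hz, exponent 1. Ground-truth phase
  traces are returned with the signal.
- **Spikes**: inhomogeneous Poisson with von Mises phase tuning,
  intensity `r0 * exp(kappa*cos(phi - mu)) / I0(kappa)` (integrates to
  `r0` per cycle), sampled by thinning. Each stimulation pulse evokes one
  extra spike with probability `evoked_probability` (default 0.6) at
  `evoked_latency_ms` (default 3 ms, inside the <5 ms window typical of
  direct optogenetic activation).
- **Head trajectory**: 120 frames/s; speed is `baseline_speed` times a
  per-condition multiplier (defaults: no-stim 1.0, peak 0.93, trough 1.4)
  times a smooth positive modulation (Ornstein-Uhlenbeck, CV 0.2,
  correlation time 0.5 s); heading is a correlated random walk on the
  unit sphere. Frame-to-frame displacement reproduces the commanded speed
  exactly, so speed recovery is unbiased.

Closed-loop simulations run at 1 kHz sampling. Acquisition hardware for
such experiments records at 24–30 kHz, and the generator supports any
rate, but phase estimation of 4–20 Hz rhythms is conventionally done on
decimated ~1 kHz data and the loop's timing granularity (10 ms hops,
sample-resolution scheduling) is unaffected. Standard problem sizes: 300 s
records for accuracy runs, six 90-s sessions (three 30-s epochs each) for
the pipeline, 60–120 s for property tests.

What the generator does *not* emulate: cross-frequency coupling, rhythm
bursting/amplitude intermittency beyond slow OU modulation, non-Poisson
spike history dependence (refractoriness, bursting), electrode artifacts,
or volume-conducted stimulation artifacts in the LFP. Passing tests
therefore demonstrate correct latency bookkeeping, unbiased phase
targeting, and correct statistics under the assumed signal model — not
performance on any particular real recording.

## Analytics

- **PSD**: Welch averaged periodogram, Hann taper, default 4 s segments
  with 50% overlap; integrated PSD matches signal variance (Parseval) to
  within sampling error.
- **Spike-field coherence**: magnitude-squared coherence between the
  1 ms-binned, mean-subtracted spike train and the LFP resampled onto the
  bin grid; cross/auto spectra averaged over windows (default 5 s, Hann).
  Windows containing no spikes are excluded; with fewer than two usable
  windows the value is *indeterminate* and reported as NaN (a single
  window gives a trivial coherence of 1), mirroring how the quantity
  becomes undefined during sparse firing in real sessions. A sliding
  variant scores each window from sub-windows for time-resolved traces.
  Absolute values depend on the estimator's window length and are not
  comparable across conventions; only contrasts and orderings are
  asserted.
- **Head speed**: Euclidean frame-to-frame displacement × frame rate,
  centered moving average over 12 frames (100 ms) by default; output
  length is `n_frames - 1`.
- **Condition contrasts**: per-session values optionally normalized to
  the session's no-stimulation baseline (yielding ratios near 1), then
  median and Q1–Q3 per condition, two-sided Wilcoxon rank-sum between two
  conditions, pooled-SD Cohen's d, and percent change of medians. The
  exact rank-sum null is used when there are no ties and the combined n
  is ≤ 60; otherwise the midrank normal approximation. At n = 6 per
  group, complete separation gives the exact two-sided p = 2/924 ≈ 0.002.

Circular statistics (wrapping to (-pi, pi], circular mean as the resultant
argument, circular quartiles as linear quartiles of deviations around the
mean, Rayleigh test with Zar's correction) are implemented in
`pabst.circular` and cross-checked against an independent library in the
test suite. Whether a session's "average phase difference" should be a
circular mean or median is a convention choice; the circular mean is used,
with the quartile interval always reported alongside.

## Numerical choices and degenerate inputs

- Latency components are summed exactly; the default stage medians total
  13.00 ms.
- The scheduling wait is quantized to the sample grid with a half-sample
  guard so a crossing landing exactly on a hop boundary cannot flip to a
  full-period wait through float rounding.
- Pulses are only commanded if their delivery time falls inside the
  recorded support, so the offline oracle can always score them.
- All-zero windows return amplitude 0 with the undefined-phase flag, never
  a garbage angle; empty spike trains make coherence indeterminate with a
  warning, never zero.
- Epoch sets are validated as non-overlapping on construction and on read;
  spike trains must be strictly increasing.
- The phase-random control fires on Bernoulli draws at `tolerance/pi` per
  hop — the fraction of hops a drifting phase spends inside the tolerance
  band — matching the deterministic policy's expected rate.

## Known limitations

- The fixed-center wavelet attenuates oscillators far from the band
  center; when the synthetic frequency walk parks near its reflection
  bound, wavelet and broadband-Hilbert phase legitimately diverge (circular
  RMSE can reach ~0.7 rad at SNR 2). Oracle-equivalence bounds (<0.1 rad
  noiseless, <0.3 rad at SNR 2) therefore hold for stationary band-limited
  signals; under frequency wander the closed loop still targets phase
  without bias, but with wider dispersion.
- Prediction extrapolates phase at the last estimated frequency only; no
  higher-order or model-based forecasting. Over the ~0.5 s horizon implied
  by the 4 Hz kernel's group delay, frequency drift is the dominant error
  source.
- Single-channel estimation only; no multi-channel fusion.
- The latency chain is modeled, not measured: stage durations are constants
  (the published medians by default), with no jitter model.
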
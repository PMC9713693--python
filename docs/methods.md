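# Methods

This note documents the models, numerical choices and their rationale.
It states no result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Clocks and synchronization

The electrophysiology clock is the master clock. Imaging frame times are
recovered from the recorded frame-trigger channel as rising edges (first
sample at/above threshold after a below-threshold sample; default
threshold halfway between the channel's min and max, which makes the
edges invariant to amplitude scaling). The behavioral video is mapped
onto the master clock by an affine fit — offset plus rate-correction
factor — pinned to the video frames at which the imaging laser's
infrared light first and last appears. An affine map rather than a pure
offset tolerates camera clock drift; a correction factor outside
[0.99, 1.01] is logged as a warning because it usually indicates wrong
anchor frames rather than real drift.

## LFP conditioning and band power

* Band-pass: zero-phase (forward–backward) 4th-order Butterworth,
  1–100 Hz. The high-pass edge removes DC; the low-pass edge sits well
  below the spiking band (≥500 Hz), which the filter attenuates by more
  than 20 dB.
* Wavelet: analytic Morlet with 6 cycles, evaluated in the frequency
  domain (the signal is FFT'd once per channel; each analyzed frequency
  multiplies the spectrum by the wavelet's one-sided Gaussian window).
  Amplitude is normalized so a unit-amplitude sinusoid at the analyzed
  frequency has power 1; power is exactly quadratic in signal amplitude.
  A frequency-domain implementation was chosen because time-domain CWT
  convolution is an order of magnitude slower at 10-minute sessions ×
  16 electrodes × ~80 frequencies, which matters for the multi-session
  calibration experiments; the transform is cross-checked in the test
  suite against PyWavelets' complex-Morlet CWT with matched parameters.
* Band power: the LFP is resampled to 250 Hz (polyphase), wavelet power
  is computed on a 1-Hz grid of in-band frequencies — theta 6–14, beta
  15–30, low gamma 35–55, high gamma 65–95 Hz — averaged over frequency,
  then averaged within each inter-frame interval to give one value per
  imaging frame. Interval means rather than instantaneous samples
  suppress aliasing of power fluctuations faster than the frame rate.
* Edge handling: frames whose interval touches the first or last second
  of the recording are flagged invalid (spectrogram cone of influence at
  the lowest frequencies) and excluded from correlations.

## Correlation analysis

Zero-lag Pearson coefficients for every (ROI, electrode, band) pair over
the valid frames; constant traces yield NaN (flagged and counted), never
a fabricated zero.

The null hypothesis is "no temporal alignment between this ROI and this
power trace", holding both series' autocorrelations fixed. Each ROI
trace is circularly shifted by an integer drawn uniformly from
[⌈L/10⌉, L−⌈L/10⌉] (L = number of valid frames); one set of 100 shifts
per ROI is reused across electrodes and bands. Because a circular shift
changes neither mean nor variance, the shifted-trace Pearson coefficient
equals the circular cross-correlation of the standardized series at that
lag, so all null correlations are computed exactly via FFT (validated
against directly rolled traces at 1e-10).

Empirical p-values are two-sided with the add-one rule,
p = (1 + #{|ρ₀| ≥ |ρ|})/(1 + N). With N = 100 shuffles p is discrete
with minimum 1/101, and the null exceedance rate of the 0.05 threshold
is 5/101 ≈ 0.0495 — the calibration target the acceptance suite checks
over 20 zero-coupling sessions. Benjamini–Hochberg runs per band across
the ROI × electrode pairs (a pooled-across-bands switch exists). The
"shuffled dataset" control treats shuffle #0 of each trace as the
observation and the remaining 99 as its null, mirroring how a shuffled
dataset would be analyzed end to end.

The original-vs-shuffled comparison pools all pairs' ρ per band and uses
the asymptotic two-sample KS test.

## Spike-to-ROI matching

Spikes are binned to frames as a binary series by default (a frame with
at least one spike gets a 1; a count option exists), convolved with
exp(−t/τ) truncated at 5τ (<1% residual kernel mass). Default
τ = 0.7 s, a slow-indicator (GCaMP6s-scale) value; when the imaging
pipeline that produced the ΔF/F used a specific decay constant, that
value should be supplied instead. Matching maximizes Pearson ρ over
ROIs; the ranking is invariant to pseudo-trace scaling.

## Spatial maps

Occupancy comes from the video-rate track (seconds per 25×25-px bin);
activity is each imaging frame's ΔF/F added to the bin of the
interpolated position at that frame; the rate-like map is
activity/occupancy on visited bins. Smoothing uses a Gaussian with
σ = 62.5 px whose kernel is renormalized over the visited support
(smooth(map·visited)/smooth(visited)); unvisited bins stay NaN instead
of being zero-filled, so empty corners neither dilute nor acquire rate.

Transient onsets are upward crossings of median + 3 robust SDs
(1.4826·MAD) of the trace — the threshold is configurable since
"transient" has no universal definition.

The 2-D KS statistic is the Fasano–Franceschini quadrant form: the
maximum over all data points and the four quadrant orientations of the
absolute difference between the two samples' quadrant cumulative
fractions (exactly reproduced by a brute-force scan in the tests). Since
the test is defined on point sets, each map is converted to one by
sampling bin centers with probability proportional to its non-negative
normalized activity; significance comes from label permutations of the
pooled draws (default 200, add-one rule), all seeded. Pairwise map
comparisons are BH-corrected across pairs.

## Optics QC

* Magnification: line period of the mean grid profile via
  autocorrelation with parabolic sub-pixel peak interpolation, divided
  by the grid spacing and the reference pixel scale. A peak must exceed
  both 3× a robust noise floor and 10% of the zero-lag energy;
  otherwise the image is rejected as structureless.
* FOV: rolling-minimum baseline (one grid period) subtracted, peaks
  above 10% of the profile maximum counted, FOV = count × spacing. The
  count × spacing convention (rather than extreme-peak distance) is the
  default; the distance variant is available behind a flag.
* FWHMs: spots are local maxima exceeding 5 robust SDs above background
  *and* 20% of the peak-to-background range — the second criterion
  rejects background extreme values, whose distribution is heavier-
  tailed than Gaussian in maximum projections. Five seeded
  randomly-sampled beads contribute 1-D Gaussian fits (lateral: through-
  center line profile; axial: z-profile through the brightest voxel);
  FWHM = 2√(2 ln 2)·σ. Lateral values are corrected by 1/M, axial by
  1/M²; beads whose axial profile is truncated by the stack boundary are
  skipped with a warning.

## Synthetic sessions

The generator's purpose is a testbed with known coupling, not a
biophysical LFP model. Its structure:

* **Latents.** One per band: an Ornstein–Uhlenbeck envelope
  (τ = 1 s, so band power fluctuates on calcium timescales; clipped at
  0.05) multiplying a sinusoid at the band's carrier (defaults 10, 22,
  45, 80 Hz — inside theta/beta/low-gamma/high-gamma).
* **Electrodes.** Each electrode mixes the latents with weights drawn
  once from U(0.5, 1.5), plus 1/f-shaped noise at 0.5× the latent scale,
  scaled to ~100 µV. A trigger channel carries one 1-ms pulse per frame.
* **Spiking.** ROI *i* is an inhomogeneous Poisson process on a 10-ms
  rate lattice: rate = baseline (0.5 Hz) × optional place-field gate
  + 6 Hz × Σ_b coupling[i,b] × (rectified latent_b, bin-averaged).
  ΔF/F = frame-binned spike counts filtered by the exponential calcium
  kernel (τ = 0.7 s) + white Gaussian noise (sd 0.1).
* **Behavior.** Reflecting Gaussian random walk (8 px/frame at 30 fps)
  in a 500×500-px arena; place fields are Gaussian bumps (σ = 80 px)
  multiplying the baseline rate.
* **Determinism.** All randomness flows from one root `SeedSequence`
  through named child streams, so identical config + seed is
  bit-identical and components are independently reproducible.

The gain constants were fixed once so that a coupling weight of 0.5
yields pair correlations of ρ ≈ 0.1–0.35 — the magnitude regime reported
for real simultaneous recordings — and were not revisited afterwards.

What the generator does **not** emulate, and hence what passing tests do
not establish for real data: volume-conducted LFP geometry, spike
waveforms, indicator nonlinearity and rise time (the kernel is
decay-only, deliberately matching the spike-matching analysis kernel so
that self-matches are exact at zero noise), motion artifacts,
neuropil contamination, and non-Poisson firing statistics. Conclusions
about *statistical calibration* (null behavior of the permutation test)
transfer to any stationary-ish data; conclusions about *power*
(detectable coupling strengths) are specific to this generative model.

## Default ephys rate

Synthetic sessions default to 1 kHz sampling: the analyses consume only
the 1–100 Hz LFP, and trigger edges at 1 ms resolution are two orders of
magnitude finer than a frame interval. Real recordings at tens of kHz
load through the same containers; the band-power stage resamples to
250 Hz internally regardless of input rate.

## Problem sizes

The acceptance suite runs the full study conditions — 20 null and 20
coupled sessions of 100 ROIs × 16 electrodes × 10 minutes at 15 Hz with
100 shuffles — in about five minutes; `scripts/acceptance.py` uses one
coupled session, five null sessions, ten matching seeds and both optics
fixtures, completing in a few minutes on one CPU.

## Known limitations

* The circular-shift null assumes stationarity within a session; strong
  slow drift in ΔF/F inflates null correlations for both observed and
  shuffled data, which preserves calibration but reduces power.
* The 2-D KS permutation p is resolution-limited by the number of
  permutations (minimum 1/(1+N)); for survey-scale map comparisons,
  raise `n_permutations`.
* Bead-based FWHM estimation assumes well-separated beads; clustered
  beads bias fits wide.
* The spectrogram's 1-Hz analysis grid undersamples theta's lower edge
  sharpness; band-power ratios between adjacent bands (theta vs beta)
  inherit some Morlet spectral leakage at 6 cycles.
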
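"""LFP conditioning, Morlet wavelet spectrograms, band-power traces.

The low-frequency (1–100 Hz) field potential is isolated with a
zero-phase band-pass, its time–frequency power is computed with an
analytic Morlet wavelet (6 cycles), and per-band power is averaged over
in-band frequencies and within inter-frame intervals to yield one value
per imaging frame — the quantity correlated against ΔF/F.

The wavelet transform is evaluated in the frequency domain: the signal is
FFT'd once and multiplied per frequency with the wavelet's Gaussian
spectral window (a one-sided Gaussian centered on the target frequency),
which makes long recordings at many frequencies cheap. Amplitude is
normalized so that a unit sinusoid at the analyzed frequency yields unit
analytic amplitude (power 1).
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .containers import CANONICAL_BANDS, BandPowerSet, EphysRecording

__all__ = [
    "extract_lfp",
    "wavelet_spectrogram",
    "band_power_traces",
    "band_power_from_spectrogram",
    "mean_spectrogram",
    "CANONICAL_BANDS",
]

#: seconds trimmed at each end of a recording when mapping power onto
#: frames: the spectrogram cone-of-influence at the lowest analyzed
#: frequencies is of this order.
EDGE_MARGIN_S = 1.0

N_CYCLES = 6.0  # Morlet width: cycles within one Gaussian SD envelope pair


def extract_lfp(rec, lo_hz: float = 1.0, hi_hz: float = 100.0) -> np.ndarray:
    """Zero-phase band-pass of the raw voltage to the LFP band.

    Forward-backward 4th-order Butterworth; output length equals the
    input length and DC is removed by the high-pass edge.
    """
    if not isinstance(rec, EphysRecording):
        raise TypeError("extract_lfp expects an EphysRecording")
    nyq = rec.rate_hz / 2.0
    if hi_hz >= nyq:
        raise ValueError(
            f"upper edge {hi_hz} Hz is at/above Nyquist ({nyq} Hz)"
        )
    if not (0 < lo_hz < hi_hz):
        raise ValueError("need 0 < lo_hz < hi_hz")
    sos = signal.butter(
        4, [lo_hz, hi_hz], btype="bandpass", fs=rec.rate_hz, output="sos"
    )
    return signal.sosfiltfilt(sos, rec.voltage_uv, axis=-1)


def _morlet_windows(n, rate_hz, freqs_hz):
    """One-sided Gaussian spectral windows of the analytic Morlet wavelet."""
    w = 2.0 * np.pi * np.fft.fftfreq(n, d=1.0 / rate_hz)
    wins = np.empty((len(freqs_hz), n))
    w0 = N_CYCLES
    for i, f in enumerate(freqs_hz):
        s = w0 / (2.0 * np.pi * f)
        wins[i] = np.where(w > 0, 2.0 * np.exp(-0.5 * (s * w - w0) ** 2), 0.0)
    return wins


def wavelet_spectrogram(
    lfp_channel: np.ndarray, rate_hz: float, freqs_hz
) -> np.ndarray:
    """Morlet wavelet power of one channel.

    Returns a (n_samples, n_freqs) array of squared analytic amplitude;
    the time axis is the sample axis of the input.
    """
    x = np.asarray(lfp_channel, dtype=float)
    if x.ndim != 1:
        raise ValueError("lfp_channel must be one-dimensional")
    freqs = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    if freqs.size == 0:
        raise ValueError("freqs_hz must not be empty")
    nyq = rate_hz / 2.0
    if np.any(freqs <= 0) or np.any(freqs >= nyq):
        raise ValueError(f"frequencies must lie in (0, {nyq}) Hz")
    n = x.size
    X = np.fft.fft(x)
    wins = _morlet_windows(n, rate_hz, freqs)
    out = np.empty((n, freqs.size))
    for i in range(freqs.size):
        coef = np.fft.ifft(X * wins[i])
        out[:, i] = np.abs(coef) ** 2
    return out


def mean_spectrogram(
    rec: EphysRecording,
    freqs_hz=None,
    lo_hz: float = 1.0,
    hi_hz: float = 100.0,
    analysis_rate_hz: float = 250.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Arithmetic mean over electrodes of per-electrode wavelet power.

    The LFP is band-passed and decimated to ``analysis_rate_hz`` first.
    Returns ``(power, times_s, freqs_hz)`` with power (n_times, n_freqs).
    """
    if rec.n_electrodes < 1:
        raise ValueError("recording has no channels")
    if freqs_hz is None:
        freqs_hz = np.arange(1.0, 100.0)
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    lfp, fs = _conditioned(rec, lo_hz, hi_hz, analysis_rate_hz)
    acc = None
    for e in range(lfp.shape[0]):
        p = wavelet_spectrogram(lfp[e], fs, freqs_hz)
        acc = p if acc is None else acc + p
    power = acc / lfp.shape[0]
    times = np.arange(power.shape[0]) / fs
    return power, times, freqs_hz


def _conditioned(rec, lo_hz, hi_hz, analysis_rate_hz):
    """Band-pass then decimate to the analysis rate (if beneficial)."""
    lfp = extract_lfp(rec, lo_hz, hi_hz)
    fs = rec.rate_hz
    if analysis_rate_hz and analysis_rate_hz < fs:
        q = fs / analysis_rate_hz
        up, down = 1, int(round(q))
        if abs(q - down) > 1e-9:
            # non-integer ratio: use rational resampling at 1 Hz precision
            up, down = int(round(analysis_rate_hz)), int(round(fs))
        lfp = signal.resample_poly(lfp, up, down, axis=-1)
        fs = fs * up / down
    return lfp, fs


def band_power_traces(
    rec_or_lfp,
    frame_times_s,
    band_defs=CANONICAL_BANDS,
    rate_hz: float | None = None,
    analysis_rate_hz: float = 250.0,
    freq_step_hz: float = 1.0,
    log_power: bool = False,
    edge_margin_s: float = EDGE_MARGIN_S,
) -> BandPowerSet:
    """Per-electrode, per-band LFP power aligned to imaging frames.

    For each band, wavelet power on a ``freq_step_hz``-spaced grid of
    in-band frequencies is averaged over frequency, then averaged within
    each inter-frame interval so the output frame axis matches the ΔF/F
    frame axis exactly. Frames whose interval touches the first/last
    ``edge_margin_s`` of the recording are marked invalid (cone of
    influence) and excluded from downstream correlations.

    Parameters
    ----------
    rec_or_lfp : EphysRecording or ndarray
        Recording, or pre-conditioned (n_electrodes, n_samples) LFP array
        (then ``rate_hz`` is required and no filtering is applied).
    """
    frame_times = np.asarray(frame_times_s, dtype=float)
    if isinstance(rec_or_lfp, EphysRecording):
        lfp, fs = _conditioned(rec_or_lfp, 1.0, 100.0, analysis_rate_hz)
        total_s = rec_or_lfp.duration_s
    else:
        if rate_hz is None:
            raise ValueError("rate_hz is required for a plain LFP array")
        lfp = np.atleast_2d(np.asarray(rec_or_lfp, dtype=float))
        fs = rate_hz
        total_s = lfp.shape[1] / fs

    bad = (frame_times < 0) | (frame_times > total_s)
    if np.any(bad):
        raise ValueError(
            f"frame times outside the recording span [0, {total_s:.3f}] s: "
            f"{frame_times[bad][:10]}"
        )

    n_el = lfp.shape[0]
    n_frames = frame_times.size
    n_bands = len(band_defs)
    dt_f = np.median(np.diff(frame_times)) if n_frames > 1 else total_s
    edges = np.append(frame_times, frame_times[-1] + dt_f)

    sample_t = np.arange(lfp.shape[1]) / fs
    idx = np.searchsorted(edges, sample_t, side="right") - 1
    inside = (idx >= 0) & (idx < n_frames)
    counts = np.bincount(idx[inside], minlength=n_frames).astype(float)
    counts[counts == 0] = np.nan

    freq_grids = [
        np.arange(b.lo_hz, b.hi_hz + 1e-9, freq_step_hz) for b in band_defs
    ]
    n = lfp.shape[1]
    band_wins = [_morlet_windows(n, fs, grid) for grid in freq_grids]
    power = np.empty((n_el, n_bands, n_frames))
    for e in range(n_el):
        X = np.fft.fft(lfp[e])
        for b, grid in enumerate(freq_grids):
            wins = band_wins[b]
            acc = np.zeros(n)
            for win in wins:
                acc += np.abs(np.fft.ifft(X * win)) ** 2
            band_p = acc / len(grid)
            if log_power:
                band_p = np.log10(band_p + 1e-12)
            sums = np.bincount(
                idx[inside], weights=band_p[inside], minlength=n_frames
            )
            power[e, b] = sums / counts
    # any frame with no samples inherits its neighbor (rare: rate mismatch)
    if np.any(np.isnan(power)):
        for e in range(n_el):
            for b in range(n_bands):
                row = power[e, b]
                nans = np.isnan(row)
                if nans.any():
                    row[nans] = np.interp(
                        frame_times[nans], frame_times[~nans], row[~nans]
                    )
    if log_power:
        power -= power.min()  # keep the non-negativity contract

    valid = (frame_times >= edge_margin_s) & (
        edges[1:] <= total_s - edge_margin_s
    )
    return BandPowerSet(
        power=power,
        frame_times_s=frame_times,
        band_defs=tuple(band_defs),
        valid=valid,
    )


def band_power_from_spectrogram(
    power_tf: np.ndarray,
    times_s: np.ndarray,
    freqs_hz: np.ndarray,
    frame_times_s,
    band_defs=CANONICAL_BANDS,
    edge_margin_s: float = EDGE_MARGIN_S,
) -> BandPowerSet:
    """Reduce an existing (time, frequency) spectrogram of one channel to
    a single-electrode :class:`BandPowerSet` on the imaging frame axis."""
    power_tf = np.asarray(power_tf, dtype=float)
    times = np.asarray(times_s, dtype=float)
    freqs = np.asarray(freqs_hz, dtype=float)
    frame_times = np.asarray(frame_times_s, dtype=float)
    total_s = times[-1]
    if np.any((frame_times < times[0]) | (frame_times > total_s)):
        raise ValueError("frame times outside the spectrogram span")
    n_frames = frame_times.size
    dt_f = np.median(np.diff(frame_times)) if n_frames > 1 else total_s
    edges = np.append(frame_times, frame_times[-1] + dt_f)
    idx = np.searchsorted(edges, times, side="right") - 1
    inside = (idx >= 0) & (idx < n_frames)
    counts = np.bincount(idx[inside], minlength=n_frames).astype(float)
    counts[counts == 0] = np.nan
    out = np.empty((1, len(band_defs), n_frames))
    for b, bd in enumerate(band_defs):
        sel = (freqs >= bd.lo_hz) & (freqs <= bd.hi_hz)
        if not sel.any():
            raise ValueError(f"no spectrogram frequencies inside {bd.name}")
        series = power_tf[:, sel].mean(axis=1)
        sums = np.bincount(idx[inside], weights=series[inside], minlength=n_frames)
        out[0, b] = sums / counts
    valid = (frame_times >= edge_margin_s) & (
        edges[1:] <= total_s - edge_margin_s
    )
    return BandPowerSet(
        power=out,
        frame_times_s=frame_times,
        band_defs=tuple(band_defs),
        valid=valid,
    )
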
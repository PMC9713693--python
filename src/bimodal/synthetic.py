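"""Synthetic bimodal sessions with known ground-truth coupling.

The generator emulates a head-mounted implant session: ~100 ROIs of
GCaMP-like ΔF/F, 16 electrodes in 4 tetrodes, a frame-trigger channel, and
an optional head-position track in an arena. A small set of band-limited
latent oscillations drives both modalities:

* each band latent is an amplitude-modulated carrier — an Ornstein–
  Uhlenbeck envelope (correlation time ~1 s, so band power fluctuates on
  calcium timescales) multiplying a sinusoid at the band's carrier
  frequency;
* every electrode sees a fixed random mixture of the latents plus
  1/f-shaped noise;
* ROI *i* fires as an inhomogeneous Poisson process whose rate is a
  baseline plus ``coupling[i, b]`` times the rectified band-*b* latent;
  ΔF/F is the spike train convolved with a single-exponential calcium
  kernel plus white Gaussian noise.

ROIs coupled to a band therefore co-fluctuate with that band's LFP power,
with a strength set by the coupling weight — the ground truth that the
correlation analysis is expected to recover.

The module also renders calibration targets for the optics QC: a 50-µm
grid slide image and 3-D stacks of sub-resolution fluorescent beads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .containers import (
    CANONICAL_BANDS,
    BehaviorTrack,
    EphysRecording,
    SpikeTrain,
    SpikeTrainSet,
    TraceSet,
)

__all__ = [
    "SessionConfig",
    "GroundTruth",
    "generate_session",
    "generate_grid_image",
    "generate_bead_stack",
    "BeadStack",
]

#: default carrier frequency (Hz) per canonical band
DEFAULT_LATENT_FREQS = (10.0, 22.0, 45.0, 80.0)

TRIGGER_HIGH = 5.0  # trigger pulse amplitude, volts
TRIGGER_WIDTH_S = 1e-3


@dataclass
class SessionConfig:
    """Parameters of one synthetic session.

    ``coupling_matrix`` has shape (n_rois, n_bands) with weights in [0, 1];
    zero everywhere yields a null session in which ΔF/F and LFP power share
    no drive. ``place_field_centers`` (n_rois, 2, pixels; NaN rows = no
    field) gates the baseline firing rate by a Gaussian bump of the
    animal's distance to the field center.
    """

    n_rois: int = 100
    n_electrodes: int = 16
    duration_s: float = 600.0
    imaging_rate_hz: float = 15.0
    ephys_rate_hz: float = 1000.0
    video_rate_hz: float = 30.0
    coupling_matrix: np.ndarray | None = None
    latent_freqs_hz: tuple = DEFAULT_LATENT_FREQS
    noise_sd: float = 0.1
    decay_tau_s: float = 0.7
    arena_px: tuple = (500, 500)
    place_field_centers: np.ndarray | None = None
    seed: int = 0
    # generative constants (documented defaults, rarely changed)
    baseline_rate_hz: float = 0.5
    coupling_gain_hz: float = 6.0
    envelope_tau_s: float = 1.0
    electrode_noise_sd: float = 0.5
    electrode_scale_uv: float = 100.0
    place_sigma_px: float = 80.0
    walk_step_px: float = 8.0

    def __post_init__(self):
        for name in (
            "duration_s",
            "imaging_rate_hz",
            "ephys_rate_hz",
            "video_rate_hz",
            "noise_sd",
            "decay_tau_s",
        ):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        for name in ("imaging_rate_hz", "ephys_rate_hz", "video_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_rois < 1 or self.n_electrodes < 1:
            raise ValueError("need at least one ROI and one electrode")
        if self.coupling_matrix is None:
            self.coupling_matrix = np.zeros(
                (self.n_rois, len(self.latent_freqs_hz))
            )
        self.coupling_matrix = np.asarray(self.coupling_matrix, dtype=float)
        if self.coupling_matrix.shape != (
            self.n_rois,
            len(self.latent_freqs_hz),
        ):
            raise ValueError(
                "coupling_matrix must have shape (n_rois, n_bands)"
            )
        if not np.all(np.isfinite(self.coupling_matrix)):
            raise ValueError("coupling weights must be finite")
        if self.place_field_centers is not None:
            self.place_field_centers = np.asarray(
                self.place_field_centers, dtype=float
            )
            if self.place_field_centers.shape != (self.n_rois, 2):
                raise ValueError(
                    "place_field_centers must have shape (n_rois, 2)"
                )


@dataclass
class GroundTruth:
    """What the generator actually injected, for verification downstream."""

    latent_drives: dict  # band name -> ndarray at ephys rate
    spike_times: dict  # roi id -> ndarray of seconds
    coupling_matrix: np.ndarray
    place_field_centers: np.ndarray | None
    latent_freqs_hz: tuple
    band_names: tuple = field(
        default_factory=lambda: tuple(b.name for b in CANONICAL_BANDS)
    )


def _ou_envelope(n, dt, tau, rng):
    """Ornstein–Uhlenbeck process (mean 0, unit variance) via AR(1)."""
    a = math.exp(-dt / tau)
    innov = rng.standard_normal(n) * math.sqrt(1.0 - a * a)
    x = signal.lfilter([1.0], [1.0, -a], innov)
    return x


def _pink_noise(n, rng, exponent=1.0):
    """1/f^exponent-shaped Gaussian noise, unit standard deviation."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shaping = np.ones_like(f)
    shaping[1:] = f[1:] ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _reflect(pos, lo, hi):
    """Reflect positions into [lo, hi] (period-2 triangular fold)."""
    span = hi - lo
    y = np.mod(pos - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return y + lo


def generate_session(config: SessionConfig):
    """Generate one coupled calcium/ephys/behavior session.

    Returns
    -------
    (TraceSet, EphysRecording, SpikeTrainSet, BehaviorTrack, GroundTruth)

    Identical ``config`` (including ``seed``) gives bit-identical output:
    all randomness flows from a single root seed through named child
    streams, so each component is reproducible independently.
    """
    cfg = config
    fs = cfg.ephys_rate_hz
    n_samp = int(round(cfg.duration_s * fs))
    n_frames = int(math.floor(cfg.duration_s * cfg.imaging_rate_hz))
    n_video = int(math.floor(cfg.duration_s * cfg.video_rate_hz))
    n_bands = len(cfg.latent_freqs_hz)

    root = np.random.SeedSequence(cfg.seed)
    seq_latent, seq_elec, seq_spikes, seq_noise, seq_walk = root.spawn(5)
    rng_latent = np.random.default_rng(seq_latent)
    rng_elec = np.random.default_rng(seq_elec)
    rng_spikes = np.random.default_rng(seq_spikes)
    rng_noise = np.random.default_rng(seq_noise)
    rng_walk = np.random.default_rng(seq_walk)

    # ---- band latents: OU envelope x sinusoidal carrier -----------------
    t = np.arange(n_samp) / fs
    latents = np.empty((n_bands, n_samp))
    for b, f_b in enumerate(cfg.latent_freqs_hz):
        env = 1.0 + 0.5 * _ou_envelope(n_samp, 1.0 / fs, cfg.envelope_tau_s, rng_latent)
        env = np.clip(env, 0.05, None)
        phase = rng_latent.uniform(0, 2 * np.pi)
        latents[b] = env * np.sin(2 * np.pi * f_b * t + phase)

    # ---- behavior track (needed before spikes if place fields) ----------
    w, h = cfg.arena_px
    steps = rng_walk.standard_normal((n_video, 2)) * cfg.walk_step_px
    steps[0] = 0
    start = np.array([w / 2.0, h / 2.0]) + rng_walk.uniform(-w / 4, w / 4, 2)
    raw = start + np.cumsum(steps, axis=0)
    xy = np.column_stack(
        [_reflect(raw[:, 0], 0.0, float(w)), _reflect(raw[:, 1], 0.0, float(h))]
    )
    track = BehaviorTrack(
        times_s=np.arange(n_video) / cfg.video_rate_hz,
        xy_px=xy,
        sync_offset_s=0.0,
    )

    # ---- spikes: inhomogeneous Poisson on a 10-ms rate lattice ----------
    dt_r = 0.01
    n_lat = int(round(cfg.duration_s / dt_r))
    # rectified latent, averaged within each lattice bin
    per_bin = max(1, int(round(dt_r * fs)))
    usable = n_lat * per_bin
    rect = np.maximum(latents[:, :usable], 0.0)
    rect_bin = rect.reshape(n_bands, n_lat, per_bin).mean(axis=2)

    t_lat = (np.arange(n_lat) + 0.5) * dt_r
    base = np.full((cfg.n_rois, n_lat), cfg.baseline_rate_hz)
    if cfg.place_field_centers is not None:
        px = np.interp(t_lat, track.times_s, track.xy_px[:, 0])
        py = np.interp(t_lat, track.times_s, track.xy_px[:, 1])
        for i in range(cfg.n_rois):
            c = cfg.place_field_centers[i]
            if np.all(np.isfinite(c)):
                d2 = (px - c[0]) ** 2 + (py - c[1]) ** 2
                base[i] *= np.exp(-d2 / (2.0 * cfg.place_sigma_px**2))
    rate = base + cfg.coupling_gain_hz * (cfg.coupling_matrix @ rect_bin)

    counts = rng_spikes.poisson(rate * dt_r)
    spike_times = {}
    units = []
    for i in range(cfg.n_rois):
        k = counts[i]
        total = int(k.sum())
        if total:
            bins = np.repeat(np.arange(n_lat), k)
            times = (bins + rng_spikes.uniform(size=total)) * dt_r
            times = np.sort(times)
            # enforce strict increase (ties have measure zero but be safe)
            eps = 1e-9
            for j in range(1, times.size):
                if times[j] <= times[j - 1]:
                    times[j] = times[j - 1] + eps
        else:
            times = np.empty(0)
        spike_times[i] = times
        units.append(SpikeTrain(unit_id=i, spike_times_s=times, tetrode=i % 4))

    # ---- ΔF/F: spike counts per frame -> exponential kernel + noise -----
    frame_times = np.arange(n_frames) / cfg.imaging_rate_hz
    dt_f = 1.0 / cfg.imaging_rate_hz
    a = math.exp(-dt_f / cfg.decay_tau_s)
    dff = np.empty((cfg.n_rois, n_frames))
    edges = np.arange(n_frames + 1) * dt_f
    for i in range(cfg.n_rois):
        binned = np.histogram(spike_times[i], bins=edges)[0].astype(float)
        dff[i] = signal.lfilter([1.0], [1.0, -a], binned)
    if cfg.noise_sd > 0:
        dff += rng_noise.standard_normal(dff.shape) * cfg.noise_sd

    roi_centroids = rng_noise.uniform(0, 512, size=(cfg.n_rois, 2))
    traces = TraceSet(
        dff=dff,
        frame_times_s=frame_times,
        roi_ids=np.arange(cfg.n_rois),
        roi_centroids_px=roi_centroids,
    )

    # ---- electrode voltages: mixed latents + 1/f noise ------------------
    weights = rng_elec.uniform(0.5, 1.5, size=(cfg.n_electrodes, n_bands))
    voltage = weights @ latents
    for e in range(cfg.n_electrodes):
        voltage[e] += cfg.electrode_noise_sd * _pink_noise(n_samp, rng_elec)
    voltage *= cfg.electrode_scale_uv

    trigger = np.zeros(n_samp)
    width = max(1, int(round(TRIGGER_WIDTH_S * fs)))
    onsets = np.round(frame_times * fs).astype(int)
    for s in onsets:
        trigger[s : s + width] = TRIGGER_HIGH

    rec = EphysRecording(
        voltage_uv=voltage,
        rate_hz=fs,
        tetrode_of=np.arange(cfg.n_electrodes) // 4,
        trigger=trigger,
    )

    band_names = tuple(b.name for b in CANONICAL_BANDS)[:n_bands]
    truth = GroundTruth(
        latent_drives={band_names[b]: latents[b] for b in range(n_bands)},
        spike_times=spike_times,
        coupling_matrix=cfg.coupling_matrix.copy(),
        place_field_centers=(
            None
            if cfg.place_field_centers is None
            else cfg.place_field_centers.copy()
        ),
        latent_freqs_hz=tuple(cfg.latent_freqs_hz),
        band_names=band_names,
    )

    return traces, rec, SpikeTrainSet(units), track, truth


# ---------------------------------------------------------------------------
# optics calibration targets
# ---------------------------------------------------------------------------


def generate_grid_image(
    spacing_um: float,
    px_per_um: float,
    n_lines: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    height_px: int = 256,
    line_sigma_px: float = 1.5,
    amplitude: float = 100.0,
) -> np.ndarray:
    """Render a calibration grid-slide image: bright vertical lines every
    ``spacing_um * px_per_um`` pixels, ``n_lines`` of them, plus Gaussian
    noise. Deterministic per seed."""
    if spacing_um <= 0 or px_per_um <= 0:
        raise ValueError("spacing_um and px_per_um must be > 0")
    period_px = spacing_um * px_per_um
    if period_px < 2:
        raise ValueError(
            f"grid period {period_px:.2f} px is finer than 2 px and cannot "
            "be resolved"
        )
    if n_lines < 1:
        raise ValueError("need at least one line")
    width_px = int(round(period_px * n_lines))
    x = np.arange(width_px)
    profile = np.zeros(width_px)
    for j in range(n_lines):
        center = (j + 0.5) * period_px
        profile += np.exp(-((x - center) ** 2) / (2 * line_sigma_px**2))
    img = np.tile(profile * amplitude, (height_px, 1))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.standard_normal(img.shape) * noise_sd
    return img


@dataclass
class BeadStack:
    """Synthetic 3-D bead stack with the true bead positions attached."""

    data: np.ndarray  # (nz, ny, nx)
    positions: np.ndarray  # (n_beads, 3) as (z, y, x) in voxel units
    px_per_um: float
    z_step_um: float
    fwhm_xy_um: float
    fwhm_z_um: float

    def max_projection(self) -> np.ndarray:
        return self.data.max(axis=0)


_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


def generate_bead_stack(
    fwhm_xy_um: float,
    fwhm_z_um: float,
    n_beads: int,
    px_per_um: float,
    z_step_um: float,
    seed: int = 0,
    noise_sd: float = 0.0,
    shape_xy: int = 256,
    positions: np.ndarray | None = None,
) -> BeadStack:
    """Render a 3-D stack of Gaussian bead images with the requested
    apparent lateral/axial FWHMs at non-overlapping random positions.

    ``positions`` (z, y, x voxels) overrides random placement. Raises if
    the beads cannot be placed without overlap.
    """
    if fwhm_xy_um <= 0 or fwhm_z_um <= 0:
        raise ValueError("FWHMs must be > 0")
    sigma_xy = fwhm_xy_um * px_per_um / _FWHM
    sigma_z = fwhm_z_um / z_step_um / _FWHM
    nz = max(15, int(round(5.0 * fwhm_z_um / z_step_um)) | 1)
    ny = nx = shape_xy
    rng = np.random.default_rng(seed)

    margin_xy = 4.0 * sigma_xy + 2.0
    margin_z = 2.5 * sigma_z
    if positions is None:
        if margin_xy > (nx - 1) / 2.0 or margin_z > (nz - 1) / 2.0:
            raise ValueError(
                "field too small to place any non-overlapping bead with "
                f"FWHM {fwhm_xy_um} um at {px_per_um} px/um"
            )
        min_sep = 8.0 * sigma_xy + 4.0
        placed = []
        tries = 0
        while len(placed) < n_beads:
            tries += 1
            if tries > 20000:
                raise ValueError(
                    f"could not place {n_beads} non-overlapping beads in a "
                    f"{ny}x{nx} field (placed {len(placed)})"
                )
            cand = np.array(
                [
                    rng.uniform(margin_z, nz - 1 - margin_z),
                    rng.uniform(margin_xy, ny - 1 - margin_xy),
                    rng.uniform(margin_xy, nx - 1 - margin_xy),
                ]
            )
            if all(
                np.hypot(cand[1] - p[1], cand[2] - p[2]) >= min_sep
                for p in placed
            ):
                placed.append(cand)
        positions = np.array(placed)
    else:
        positions = np.asarray(positions, dtype=float)

    amps = rng.uniform(80.0, 120.0, size=len(positions))
    stack = np.zeros((nz, ny, nx))
    zi = np.arange(nz)
    yi = np.arange(ny)
    xi = np.arange(nx)
    for (cz, cy, cx), amp in zip(positions, amps):
        gz = np.exp(-((zi - cz) ** 2) / (2 * sigma_z**2))
        gy = np.exp(-((yi - cy) ** 2) / (2 * sigma_xy**2))
        gx = np.exp(-((xi - cx) ** 2) / (2 * sigma_xy**2))
        stack += amp * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    if noise_sd > 0:
        stack = stack + rng.standard_normal(stack.shape) * noise_sd
    return BeadStack(
        data=stack,
        positions=positions,
        px_per_um=px_per_um,
        z_step_um=z_step_um,
        fwhm_xy_um=fwhm_xy_um,
        fwhm_z_um=fwhm_z_um,
    )


def null_config(**overrides) -> SessionConfig:
    """A zero-coupling control session (100 ROIs, 16 electrodes, 10 min)."""
    return SessionConfig(**overrides)


def coupled_config(
    coupled_fraction: float = 0.5,
    weight: float = 0.5,
    band: int = 0,
    **overrides,
) -> SessionConfig:
    """Session with the first ``coupled_fraction`` of ROIs coupled at
    ``weight`` to one band latent (theta by default)."""
    cfg = SessionConfig(**overrides)
    n_coupled = int(round(cfg.n_rois * coupled_fraction))
    coupling = np.zeros((cfg.n_rois, len(cfg.latent_freqs_hz)))
    coupling[:n_coupled, band] = weight
    return replace(cfg, coupling_matrix=coupling)
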
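"""In-memory containers shared across the analysis modules.

All time series carry explicit timestamps in seconds. The electrophysiology
clock is the master clock of a session: imaging frame times and behavior
track times are expressed on (or carry an offset onto) that clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TraceSet",
    "EphysRecording",
    "SpikeTrain",
    "SpikeTrainSet",
    "BehaviorTrack",
    "BandDef",
    "CANONICAL_BANDS",
    "BandPowerSet",
    "CorrelationResult",
    "SpatialMap",
    "OpticsReport",
]


@dataclass
class TraceSet:
    """Per-ROI ΔF/F traces sampled on the imaging frame clock.

    Attributes
    ----------
    dff : ndarray, shape (n_rois, n_frames)
        Fractional fluorescence change, dimensionless.
    frame_times_s : ndarray, shape (n_frames,)
        Frame timestamps in seconds on the master (ephys) clock,
        strictly increasing.
    roi_ids : ndarray of int, shape (n_rois,)
    roi_centroids_px : ndarray, shape (n_rois, 2), optional
        (x, y) centroids in image pixels.
    """

    dff: np.ndarray
    frame_times_s: np.ndarray
    roi_ids: np.ndarray = None
    roi_centroids_px: np.ndarray | None = None

    def __post_init__(self):
        self.dff = np.atleast_2d(np.asarray(self.dff, dtype=float))
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        if self.roi_ids is None:
            self.roi_ids = np.arange(self.dff.shape[0])
        self.roi_ids = np.asarray(self.roi_ids)
        self.validate()

    def validate(self):
        if self.dff.shape[1] != self.frame_times_s.size:
            raise ValueError(
                f"dff has {self.dff.shape[1]} frames but "
                f"{self.frame_times_s.size} frame times"
            )
        if self.dff.shape[0] != self.roi_ids.size:
            raise ValueError("number of ROI ids does not match dff rows")
        if not np.all(np.diff(self.frame_times_s) > 0):
            raise ValueError("frame_times_s must be strictly increasing")
        if not np.all(np.isfinite(self.dff)):
            bad = np.argwhere(~np.isfinite(self.dff))
            roi, frame = bad[0]
            raise ValueError(
                f"non-finite ΔF/F values at {len(bad)} positions, first at "
                f"ROI {self.roi_ids[roi]}, frame {frame}"
            )

    @property
    def n_rois(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]


@dataclass
class EphysRecording:
    """Multi-electrode voltage recording with optional frame-trigger channel.

    Attributes
    ----------
    voltage_uv : ndarray, shape (n_electrodes, n_samples)
        Extracellular voltage in microvolts.
    rate_hz : float
        Sampling rate.
    tetrode_of : ndarray of int, shape (n_electrodes,)
        Tetrode index of each electrode.
    trigger : ndarray, shape (n_samples,), optional
        Imaging frame trigger channel (one pulse per frame).
    """

    voltage_uv: np.ndarray
    rate_hz: float
    tetrode_of: np.ndarray = None
    trigger: np.ndarray | None = None

    def __post_init__(self):
        self.voltage_uv = np.atleast_2d(np.asarray(self.voltage_uv, dtype=float))
        if self.rate_hz <= 0 or not np.isfinite(self.rate_hz):
            raise ValueError("rate_hz must be a positive finite number")
        n_el = self.voltage_uv.shape[0]
        if self.tetrode_of is None:
            # default grouping: consecutive blocks of four
            self.tetrode_of = np.arange(n_el) // 4
        self.tetrode_of = np.asarray(self.tetrode_of, dtype=int)
        if self.tetrode_of.size != n_el:
            raise ValueError("tetrode_of length must equal electrode count")
        if n_el == 16 and len(np.unique(self.tetrode_of)) != 4:
            raise ValueError("16 electrodes must be grouped into 4 tetrodes")
        if self.trigger is not None:
            self.trigger = np.asarray(self.trigger, dtype=float)
            if self.trigger.size != self.voltage_uv.shape[1]:
                raise ValueError("trigger length must equal sample count")

    @property
    def n_electrodes(self) -> int:
        return self.voltage_uv.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltage_uv.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    @property
    def sample_times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate_hz


@dataclass
class SpikeTrain:
    """Sorted spike times of one single unit."""

    unit_id: int
    spike_times_s: np.ndarray
    tetrode: int = -1

    def __post_init__(self):
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        if self.spike_times_s.size and not np.all(
            np.diff(self.spike_times_s) > 0
        ):
            raise ValueError(
                f"unit {self.unit_id}: spike times must be strictly increasing"
            )


@dataclass
class SpikeTrainSet:
    units: list[SpikeTrain] = field(default_factory=list)

    def __iter__(self):
        return iter(self.units)

    def __len__(self):
        return len(self.units)

    def __getitem__(self, i):
        return self.units[i]

    def unit(self, unit_id) -> SpikeTrain:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(f"no unit with id {unit_id}")


@dataclass
class BehaviorTrack:
    """Head-position track at video rate.

    ``times_s`` are on the video clock; add ``sync_offset_s`` (and apply
    ``rate_factor``) to express them on the master imaging/ephys clock.
    """

    times_s: np.ndarray
    xy_px: np.ndarray
    sync_offset_s: float = 0.0
    rate_factor: float = 1.0

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.xy_px = np.asarray(self.xy_px, dtype=float)
        if self.xy_px.shape != (self.times_s.size, 2):
            raise ValueError("xy_px must have shape (n_frames, 2)")
        if self.times_s.size > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("track timestamps must be strictly increasing")

    @property
    def times_master_s(self) -> np.ndarray:
        """Track timestamps on the master clock."""
        return self.sync_offset_s + self.rate_factor * self.times_s


@dataclass(frozen=True)
class BandDef:
    """A named LFP frequency band [lo_hz, hi_hz]."""

    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self):
        if not (0 < self.lo_hz < self.hi_hz):
            raise ValueError(f"band {self.name}: need 0 < lo < hi")


#: The canonical four-band split of the 1–100 Hz LFP used throughout:
#: theta, beta, low gamma and high gamma.
CANONICAL_BANDS = (
    BandDef("theta", 6.0, 14.0),
    BandDef("beta", 15.0, 30.0),
    BandDef("lgamma", 35.0, 55.0),
    BandDef("hgamma", 65.0, 95.0),
)


@dataclass
class BandPowerSet:
    """Per-electrode, per-band LFP power resampled to imaging frames.

    Attributes
    ----------
    power : ndarray, shape (n_electrodes, n_bands, n_frames)
        Non-negative band power, arbitrary units.
    frame_times_s : ndarray, shape (n_frames,)
        Identical to the TraceSet frame axis.
    band_defs : tuple of BandDef
    valid : ndarray of bool, shape (n_frames,)
        Frames outside the spectrogram cone-of-influence margins; only
        these frames enter correlations.
    """

    power: np.ndarray
    frame_times_s: np.ndarray
    band_defs: tuple
    valid: np.ndarray = None

    def __post_init__(self):
        self.power = np.asarray(self.power, dtype=float)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        if self.power.ndim != 3:
            raise ValueError("power must be (n_electrodes, n_bands, n_frames)")
        if self.power.shape[1] != len(self.band_defs):
            raise ValueError("power band axis does not match band_defs")
        if self.power.shape[2] != self.frame_times_s.size:
            raise ValueError("power frame axis does not match frame_times_s")
        if np.any(self.power < 0):
            raise ValueError("band power must be non-negative")
        if self.valid is None:
            self.valid = np.ones(self.frame_times_s.size, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def band_names(self) -> list[str]:
        return [b.name for b in self.band_defs]

    def band_index(self, name: str) -> int:
        try:
            return self.band_names.index(name)
        except ValueError:
            raise KeyError(f"unknown band {name!r}; have {self.band_names}")


@dataclass
class CorrelationResult:
    """ROI × electrode × band Pearson correlations with permutation nulls.

    ``rho`` and ``p_emp`` have shape (n_rois, n_electrodes, n_bands);
    entries for constant (undefined) traces are NaN, never zero-filled.
    ``null_rho`` has one extra trailing axis of length ``n_shuffles``.
    Per-band summaries: ``fraction_significant`` (Benjamini–Hochberg at
    ``fdr_q``), the matching fraction for the shuffled control dataset,
    and the two-sample KS comparison of original vs shuffled ρ.
    """

    rho: np.ndarray
    p_emp: np.ndarray
    null_rho: np.ndarray
    significant: np.ndarray
    fraction_significant: np.ndarray
    fraction_significant_shuffled: np.ndarray
    ks_stat: np.ndarray
    ks_p: np.ndarray
    band_names: list[str]
    roi_ids: np.ndarray
    n_shuffles: int
    min_shift_frac: float
    fdr_q: float
    n_constant_rois: int = 0

    def band_index(self, name: str) -> int:
        return list(self.band_names).index(name)


@dataclass
class SpatialMap:
    """Occupancy-normalized, Gaussian-smoothed spatial activity map.

    Unvisited bins are NaN in ``normalized``; they are excluded from the
    smoothing-kernel normalization rather than treated as zero activity.
    """

    occupancy_s: np.ndarray
    activity: np.ndarray
    normalized: np.ndarray
    arena_px: tuple
    bin_px: float
    sigma_px: float

    @property
    def visited(self) -> np.ndarray:
        return self.occupancy_s > 0

    def bin_centers(self):
        """(x, y) pixel coordinates of bin centers, each shaped like the map."""
        ny, nx = self.occupancy_s.shape
        xs = (np.arange(nx) + 0.5) * self.bin_px
        ys = (np.arange(ny) + 0.5) * self.bin_px
        return np.meshgrid(xs, ys)


@dataclass
class OpticsReport:
    """Optical characterization summary of one imaging system."""

    magnification: float
    fov_um: float
    lateral_fwhm_um: float
    axial_fwhm_um: float
    n_beads_used: int
    per_bead_lateral_um: np.ndarray | None = None
    per_bead_axial_um: np.ndarray | None = None

    def as_dict(self) -> dict:
        return {
            "magnification": float(self.magnification),
            "fov_um": float(self.fov_um),
            "lateral_fwhm_um": float(self.lateral_fwhm_um),
            "axial_fwhm_um": float(self.axial_fwhm_um),
            "n_beads_used": int(self.n_beads_used),
        }
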
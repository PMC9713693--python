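"""Reading/writing session directories and clock synchronization.

A session directory holds:

* ``traces.csv`` — ``frame_time_s, roi_0, …, roi_{n-1}`` (ΔF/F per frame)
* ``ephys.bin`` — little-endian int16, channel-interleaved samples
* ``meta.json`` — rate, channel map, µV-per-count, tetrode grouping
* ``spikes.csv`` — ``unit_id, tetrode, time_s`` (optional)
* ``track.csv`` — ``frame, x_px, y_px`` (optional)
* ``truth.json`` — generator ground truth (optional)

The electrophysiology clock is the master clock: imaging frame times come
from the recorded frame-trigger channel, and the behavioral video is
mapped onto it by an affine fit through the first/last laser-visible
frames.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    BehaviorTrack,
    EphysRecording,
    SpikeTrain,
    SpikeTrainSet,
    TraceSet,
)

__all__ = [
    "save_session",
    "load_session",
    "frame_times_from_trigger",
    "sync_video",
    "VideoSync",
]

log = logging.getLogger(__name__)

_EPHYS_DTYPE = np.dtype("<i2")


def save_session(
    path,
    traces: TraceSet,
    rec: EphysRecording,
    spikes: SpikeTrainSet | None = None,
    track: BehaviorTrack | None = None,
    truth: dict | None = None,
) -> Path:
    """Write a session directory in the layout described above.

    Voltage (and trigger) are quantized to int16 with a µV-per-count
    scale recorded in ``meta.json``; everything else is plain CSV/JSON.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    df = pd.DataFrame(
        traces.dff.T, columns=[f"roi_{int(i)}" for i in traces.roi_ids]
    )
    df.insert(0, "frame_time_s", traces.frame_times_s)
    df.to_csv(path / "traces.csv", index=False)

    channels = [rec.voltage_uv]
    trigger_channel = None
    if rec.trigger is not None:
        # trigger recorded in volts; store on its own scale in counts
        trig_scale = max(np.abs(rec.trigger).max(), 1e-12) / 30000.0
        channels.append((rec.trigger / trig_scale)[None, :])
        trigger_channel = rec.n_electrodes
    else:
        trig_scale = None
    uv_per_count = max(np.abs(rec.voltage_uv).max(), 1e-12) / 30000.0
    data = np.vstack(
        [np.round(rec.voltage_uv / uv_per_count)] + (
            [np.round(channels[1])] if trigger_channel is not None else []
        )
    )
    data.astype(_EPHYS_DTYPE).T.tofile(path / "ephys.bin")  # interleaved

    meta = {
        "rate_hz": float(rec.rate_hz),
        "n_channels": int(data.shape[0]),
        "uv_per_count": float(uv_per_count),
        "electrode_channels": list(range(rec.n_electrodes)),
        "tetrode_of": [int(t) for t in rec.tetrode_of],
        "trigger_channel": trigger_channel,
        "trigger_scale": trig_scale,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))

    if spikes is not None and len(spikes):
        rows = []
        for u in spikes:
            for t in u.spike_times_s:
                rows.append((u.unit_id, u.tetrode, t))
        pd.DataFrame(rows, columns=["unit_id", "tetrode", "time_s"]).to_csv(
            path / "spikes.csv", index=False
        )

    if track is not None:
        pd.DataFrame(
            {
                "frame": np.arange(track.times_s.size),
                "time_s": track.times_s,
                "x_px": track.xy_px[:, 0],
                "y_px": track.xy_px[:, 1],
            }
        ).to_csv(path / "track.csv", index=False)

    if truth is not None:
        (path / "truth.json").write_text(
            json.dumps(truth, indent=1, sort_keys=True)
        )
    return path


def load_session(path):
    """Load a session directory.

    Returns ``(TraceSet, EphysRecording, SpikeTrainSet | None,
    BehaviorTrack | None)``. Missing mandatory files raise with the file
    named; NaN in the traces raises naming the ROI and frame.
    """
    path = Path(path)
    for required in ("traces.csv", "ephys.bin", "meta.json"):
        if not (path / required).exists():
            raise FileNotFoundError(f"session is missing {required} in {path}")

    meta = json.loads((path / "meta.json").read_text())
    n_ch = int(meta["n_channels"])
    raw = np.fromfile(path / "ephys.bin", dtype=_EPHYS_DTYPE)
    if raw.size % n_ch:
        raise ValueError(
            f"ephys.bin has {raw.size} samples, not divisible by "
            f"{n_ch} channels — file truncated?"
        )
    raw = raw.reshape(-1, n_ch).T
    elec = np.asarray(meta["electrode_channels"], dtype=int)
    voltage = raw[elec].astype(float) * meta["uv_per_count"]
    trig_ch = meta.get("trigger_channel")
    trigger = None
    if trig_ch is not None:
        trigger = raw[int(trig_ch)].astype(float) * meta["trigger_scale"]
    rec = EphysRecording(
        voltage_uv=voltage,
        rate_hz=meta["rate_hz"],
        tetrode_of=np.asarray(meta["tetrode_of"], dtype=int),
        trigger=trigger,
    )

    df = pd.read_csv(path / "traces.csv")
    roi_cols = [c for c in df.columns if c.startswith("roi_")]
    dff = df[roi_cols].to_numpy().T
    if np.isnan(dff).any():
        roi, frame = np.argwhere(np.isnan(dff))[0]
        raise ValueError(
            f"NaN in traces.csv: column {roi_cols[roi]}, frame {frame}"
        )
    traces = TraceSet(
        dff=dff,
        frame_times_s=df["frame_time_s"].to_numpy(),
        roi_ids=np.array([int(c.split("_", 1)[1]) for c in roi_cols]),
    )

    spikes = None
    if (path / "spikes.csv").exists():
        sdf = pd.read_csv(path / "spikes.csv")
        units = []
        for uid, grp in sdf.groupby("unit_id"):
            units.append(
                SpikeTrain(
                    unit_id=int(uid),
                    spike_times_s=np.sort(grp["time_s"].to_numpy()),
                    tetrode=int(grp["tetrode"].iloc[0]),
                )
            )
        spikes = SpikeTrainSet(units)

    track = None
    if (path / "track.csv").exists():
        tdf = pd.read_csv(path / "track.csv")
        track = BehaviorTrack(
            times_s=tdf["time_s"].to_numpy(),
            xy_px=tdf[["x_px", "y_px"]].to_numpy(),
        )

    return traces, rec, spikes, track


def frame_times_from_trigger(
    trigger, rate_hz: float, threshold: float | None = None
) -> np.ndarray:
    """Imaging frame times from the recorded frame-trigger channel.

    A frame time is the first sample at/above ``threshold`` following a
    below-threshold sample (rising edge), in seconds on the ephys clock.
    The default threshold is halfway between the channel's min and max,
    which makes the result invariant to trigger amplitude scaling.
    """
    trig = np.asarray(trigger, dtype=float)
    if trig.size < 2:
        raise ValueError("trigger channel too short")
    if threshold is None:
        threshold = trig.min() + 0.5 * (trig.max() - trig.min())
    high = trig >= threshold
    edges = np.flatnonzero(high[1:] & ~high[:-1]) + 1
    if high[0]:
        edges = np.concatenate([[0], edges])
    if edges.size == 0:
        raise ValueError("no rising edges found in trigger channel")
    return edges / rate_hz


@dataclass(frozen=True)
class VideoSync:
    """Affine map from video-frame index to master-clock seconds:
    ``t_master = sync_offset_s + rate_factor * (frame / video_rate_hz)``."""

    sync_offset_s: float
    rate_factor: float
    video_rate_hz: float

    def frame_to_master(self, frame):
        return self.sync_offset_s + self.rate_factor * (
            np.asarray(frame, dtype=float) / self.video_rate_hz
        )


def sync_video(
    laser_on_frame: int,
    laser_off_frame: int,
    video_rate_hz: float,
    imaging_start_s: float,
    imaging_end_s: float,
) -> VideoSync:
    """Fit the video clock onto the imaging (master) clock.

    The two anchors are the video frames at which the imaging laser's
    infrared light first and last appears; they are pinned to the imaging
    start/end times. The fit is affine (offset plus rate-correction
    factor) to tolerate camera clock drift; a factor outside [0.99, 1.01]
    is logged as a warning but still returned.
    """
    if laser_on_frame >= laser_off_frame:
        raise ValueError("laser_on_frame must precede laser_off_frame")
    if imaging_start_s >= imaging_end_s:
        raise ValueError("imaging_start_s must precede imaging_end_s")
    video_span = (laser_off_frame - laser_on_frame) / video_rate_hz
    factor = (imaging_end_s - imaging_start_s) / video_span
    offset = imaging_start_s - factor * laser_on_frame / video_rate_hz
    if not (0.99 <= factor <= 1.01):
        log.warning(
            "video/imaging rate mismatch: rate-correction factor %.4f "
            "outside [0.99, 1.01]",
            factor,
        )
    return VideoSync(
        sync_offset_s=offset, rate_factor=factor, video_rate_hz=video_rate_hz
    )
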
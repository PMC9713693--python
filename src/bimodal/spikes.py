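"""Spike-train to pseudo-calcium conversion and ROI matching.

A sorted unit's spike times are binned to imaging frames as a binary
series (a frame containing at least one spike gets a one), convolved with
a single-exponential calcium kernel exp(-t/τ), and the resulting
pseudo-calcium trace is compared against every imaged ROI with Pearson's
correlation to find the optical cell that best matches the electrically
recorded unit. Pearson's scale invariance means the arbitrary amplitude
of the pseudo-trace does not affect the ranking.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .containers import SpikeTrain, TraceSet

__all__ = ["PseudoTrace", "convolve_spikes", "best_match", "MatchResult"]

log = logging.getLogger(__name__)

KERNEL_TRUNCATE_TAUS = 5.0  # < 1% of kernel mass beyond this


@dataclass
class PseudoTrace:
    """Spike train rendered as a calcium-like trace on the frame clock."""

    values: np.ndarray
    frame_times_s: np.ndarray
    decay_tau_s: float
    unit_id: int


def convolve_spikes(
    spikes: SpikeTrain,
    decay_tau_s: float,
    frame_times_s,
    binary: bool = True,
) -> PseudoTrace:
    """Convolve a spike train with an exponential decay kernel.

    Spikes are binned to frames — binary per frame by default, or counts
    with ``binary=False`` — and convolved with ``exp(-t/τ)`` evaluated at
    the frame spacing (causal: no output before a spike). Spikes outside
    the frame span are clipped with a warning.
    """
    if decay_tau_s <= 0:
        raise ValueError("decay_tau_s must be > 0")
    frame_times = np.asarray(frame_times_s, dtype=float)
    n = frame_times.size
    dt = np.median(np.diff(frame_times))
    edges = np.append(frame_times, frame_times[-1] + dt)
    t = spikes.spike_times_s
    outside = (t < edges[0]) | (t >= edges[-1])
    if outside.any():
        log.warning(
            "unit %s: clipping %d spikes outside the frame span",
            spikes.unit_id,
            int(outside.sum()),
        )
        t = t[~outside]
    binned = np.histogram(t, bins=edges)[0].astype(float)
    if binary:
        binned = (binned > 0).astype(float)
    k = int(math.ceil(KERNEL_TRUNCATE_TAUS * decay_tau_s / dt)) + 1
    kernel = np.exp(-np.arange(k) * dt / decay_tau_s)
    values = np.convolve(binned, kernel)[:n]
    return PseudoTrace(
        values=values,
        frame_times_s=frame_times,
        decay_tau_s=decay_tau_s,
        unit_id=spikes.unit_id,
    )


@dataclass
class MatchResult:
    """Ranking of imaged ROIs against one pseudo-calcium trace."""

    unit_id: int
    best_roi: int
    best_rho: float
    ranking: list  # [(roi_id, rho), ...] descending


def best_match(pseudo: PseudoTrace, traces: TraceSet) -> MatchResult:
    """Find the ROI whose ΔF/F best matches a pseudo-calcium trace.

    Pearson ρ against every ROI, returning the argmax and the full
    descending ranking. Raises if the pseudo-trace is constant (a unit
    with no spikes in the frame span has no usable signal).
    """
    if pseudo.frame_times_s.size != traces.n_frames or not np.allclose(
        pseudo.frame_times_s, traces.frame_times_s
    ):
        raise ValueError("pseudo trace and TraceSet frame axes differ")
    v = np.asarray(pseudo.values, dtype=float)
    if v.std() == 0:
        raise ValueError(
            f"unit {pseudo.unit_id}: pseudo-calcium trace is constant "
            "(no spikes?)"
        )
    vz = (v - v.mean()) / v.std()
    x = traces.dff
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        xz = np.where(sd == 0, np.nan, (x - mu) / sd)
    rho = np.nansum(xz * vz, axis=1) / v.size
    rho[np.all(~np.isfinite(xz), axis=1)] = np.nan
    finite = np.isfinite(rho)
    order = np.lexsort((traces.roi_ids, -np.where(finite, rho, -np.inf)))
    order = [i for i in order if finite[i]]
    ranking = [(int(traces.roi_ids[i]), float(rho[i])) for i in order]
    return MatchResult(
        unit_id=pseudo.unit_id,
        best_roi=ranking[0][0],
        best_rho=ranking[0][1],
        ranking=ranking,
    )
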
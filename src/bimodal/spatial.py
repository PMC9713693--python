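"""Freely-moving analyses: velocity, transient positions, spatial maps.

Activity maps follow the occupancy-normalization convention of place-cell
analysis: ΔF/F summed into 25 × 25-pixel spatial bins by the animal's
position at each imaging frame, divided by the time spent per bin, then
Gaussian-smoothed (σ = 62.5 px) with the kernel renormalized over visited
bins so that unvisited bins neither leak zeros into the map nor acquire
fabricated rate values.

Maps are compared with a two-sample two-dimensional Kolmogorov–Smirnov
test (Fasano–Franceschini variant: the statistic is the largest
difference between the two samples' quadrant cumulative fractions over
all data points), applied to activity-weighted point samples drawn from
each map, with a permutation p-value.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, stats

from .containers import BehaviorTrack, SpatialMap

__all__ = [
    "head_velocity",
    "transient_positions",
    "build_spatial_map",
    "ks2d_stat",
    "ks2d_compare",
    "pairwise_map_tests",
    "map_to_points",
]


def head_velocity(track: BehaviorTrack, smooth_window_s: float = 0.5):
    """Head speed in px/s: centered finite differences, boxcar-smoothed.

    Returns an array the length of the track.
    """
    t = track.times_s
    if t.size < 2:
        raise ValueError("need at least 2 track points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("duplicate or non-increasing track timestamps")
    vx = np.gradient(track.xy_px[:, 0], t)
    vy = np.gradient(track.xy_px[:, 1], t)
    speed = np.hypot(vx, vy)
    if smooth_window_s > 0:
        rate = 1.0 / np.median(np.diff(t))
        w = max(1, int(round(smooth_window_s * rate)))
        speed = ndimage.uniform_filter1d(speed, size=w, mode="nearest")
    return speed


def transient_positions(
    trace,
    frame_times_s,
    track: BehaviorTrack,
    threshold_sd: float = 3.0,
):
    """Arena positions at calcium-transient onsets.

    A transient onset is an upward crossing of
    ``median + threshold_sd * robust SD`` (robust SD = 1.4826·MAD) of the
    ΔF/F trace; the position is the track sample nearest in time to the
    onset frame (track times mapped onto the master clock through the
    track's sync). Returns ``(positions (n, 2), onset_times_s)``; both
    empty when nothing crosses.
    """
    x = np.asarray(trace, dtype=float)
    frame_times = np.asarray(frame_times_s, dtype=float)
    med = np.median(x)
    rsd = 1.4826 * np.median(np.abs(x - med))
    thr = med + threshold_sd * rsd
    above = x >= thr
    onsets = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        onsets = np.concatenate([[0], onsets])
    if onsets.size == 0:
        return np.empty((0, 2)), np.empty(0)
    t_on = frame_times[onsets]
    tt = track.times_master_s
    idx = np.clip(np.searchsorted(tt, t_on), 1, tt.size - 1)
    idx = np.where(
        np.abs(tt[idx - 1] - t_on) <= np.abs(tt[idx] - t_on), idx - 1, idx
    )
    return track.xy_px[idx], t_on


def build_spatial_map(
    trace,
    frame_times_s,
    track: BehaviorTrack,
    arena_px,
    bin_px: float = 25.0,
    sigma_px: float = 62.5,
) -> SpatialMap:
    """Occupancy-normalized, Gaussian-smoothed spatial activity map.

    Occupancy comes from the video-rate track (seconds per bin); activity
    is the ΔF/F value of each imaging frame added to the bin of the
    interpolated position at that frame. ``normalized`` is
    activity/occupancy on visited bins, smoothed with a σ = ``sigma_px``
    Gaussian whose kernel is renormalized over the visited support;
    unvisited bins stay NaN. ``sigma_px=0`` disables smoothing.
    """
    if bin_px <= 0:
        raise ValueError("bin_px must be > 0")
    w, h = arena_px
    nx = int(np.ceil(w / bin_px))
    ny = int(np.ceil(h / bin_px))
    x = np.asarray(trace, dtype=float)
    frame_times = np.asarray(frame_times_s, dtype=float)

    tt = track.times_master_s
    dt_video = np.median(np.diff(tt)) if tt.size > 1 else 0.0

    def bin_of(xy):
        bx = np.clip((xy[:, 0] // bin_px).astype(int), 0, nx - 1)
        by = np.clip((xy[:, 1] // bin_px).astype(int), 0, ny - 1)
        return by, bx

    occupancy = np.zeros((ny, nx))
    by, bx = bin_of(track.xy_px)
    np.add.at(occupancy, (by, bx), dt_video)

    # activity: position interpolated at imaging frame times
    keep = (frame_times >= tt[0]) & (frame_times <= tt[-1])
    fx = np.interp(frame_times[keep], tt, track.xy_px[:, 0])
    fy = np.interp(frame_times[keep], tt, track.xy_px[:, 1])
    aby, abx = bin_of(np.column_stack([fx, fy]))
    activity = np.zeros((ny, nx))
    np.add.at(activity, (aby, abx), x[keep])

    visited = occupancy > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(visited, activity / occupancy, np.nan)

    if sigma_px > 0:
        sigma_bins = sigma_px / bin_px
        filled = np.where(visited, normalized, 0.0)
        num = ndimage.gaussian_filter(filled, sigma_bins, mode="constant")
        den = ndimage.gaussian_filter(
            visited.astype(float), sigma_bins, mode="constant"
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            normalized = np.where(visited, num / den, np.nan)

    return SpatialMap(
        occupancy_s=occupancy,
        activity=activity,
        normalized=normalized,
        arena_px=tuple(arena_px),
        bin_px=bin_px,
        sigma_px=sigma_px,
    )


def ks2d_stat(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample 2D KS statistic (Fasano–Franceschini).

    The maximum, over the four closed/open quadrant orientations at every
    data point of both samples, of the absolute difference between the
    two samples' quadrant cumulative fractions.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2 or b.ndim != 2 or b.shape[1] != 2:
        raise ValueError("point sets must have shape (n, 2)")
    if len(a) == 0 or len(b) == 0:
        raise ValueError("point sets must be non-empty")
    pts = np.vstack([a, b])
    # indicator matrices over (evaluation point, pooled sample point);
    # the first len(a) columns belong to sample a
    lex = pts[None, :, 0] <= pts[:, None, 0]
    ley = pts[None, :, 1] <= pts[:, None, 1]
    return _max_quadrant_gap(lex, ley, len(a))


def _max_quadrant_gap(lex, ley, n_a):
    """Max over evaluation points/quadrants of |F_a - F_b| given indicator
    matrices over the pooled samples (first n_a columns = sample a)."""
    n_b = lex.shape[1] - n_a
    gaps = []
    for qx in (lex, ~lex):
        for qy in (ley, ~ley):
            inq = qx & qy
            fa = inq[:, :n_a].sum(axis=1) / n_a
            fb = inq[:, n_a:].sum(axis=1) / n_b
            gaps.append(np.abs(fa - fb).max())
    return max(gaps)


def map_to_points(
    spatial_map: SpatialMap, n_resample: int, rng
) -> np.ndarray:
    """Draw bin-center points from a map with probability proportional to
    its (non-negative) normalized activity."""
    xs, ys = spatial_map.bin_centers()
    w = np.nan_to_num(spatial_map.normalized, nan=0.0).ravel()
    w = np.clip(w, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise ValueError("map has zero total activity; cannot resample")
    idx = rng.choice(w.size, size=n_resample, p=w / total)
    return np.column_stack([xs.ravel()[idx], ys.ravel()[idx]])


def ks2d_compare(
    map_a: SpatialMap,
    map_b: SpatialMap,
    n_resample: int = 500,
    seed: int = 0,
    n_permutations: int = 200,
):
    """Compare two spatial maps with the 2D KS test on weighted resamples.

    ``n_resample`` points are drawn from each map proportional to its
    normalized activity; the observed statistic is compared against
    ``n_permutations`` label permutations of the pooled points. Returns
    ``(D, p)``; deterministic per seed.
    """
    if map_a.occupancy_s.shape != map_b.occupancy_s.shape:
        raise ValueError("maps must share the same bin grid")
    rng = np.random.default_rng(seed)
    pa = map_to_points(map_a, n_resample, rng)
    pb = map_to_points(map_b, n_resample, rng)
    d_obs = ks2d_stat(pa, pb)
    pooled = np.vstack([pa, pb])
    n = len(pa)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(pooled))
        d = ks2d_stat(pooled[perm[:n]], pooled[perm[n:]])
        if d >= d_obs:
            count += 1
    p = (1.0 + count) / (1.0 + n_permutations)
    return float(d_obs), float(p)


def pairwise_map_tests(
    maps: list[SpatialMap],
    n_resample: int = 500,
    seed: int = 0,
    fdr_q: float = 0.05,
    n_permutations: int = 200,
):
    """All unordered pairwise 2D KS comparisons with BH correction.

    Returns ``(D, p, significant)`` — symmetric (n_maps, n_maps) arrays
    with NaN/False on the diagonal; significance is Benjamini–Hochberg
    across the ``n(n-1)/2`` pairs at level ``fdr_q``.
    """
    from .correlate import _bh_mask

    n = len(maps)
    if n < 2:
        raise ValueError("need at least 2 maps")
    D = np.full((n, n), np.nan)
    P = np.full((n, n), np.nan)
    pair_p = []
    pairs = []
    root = np.random.SeedSequence(seed)
    seeds = root.generate_state(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            d, p = ks2d_compare(
                maps[i],
                maps[j],
                n_resample=n_resample,
                seed=int(seeds[k]),
                n_permutations=n_permutations,
            )
            D[i, j] = D[j, i] = d
            P[i, j] = P[j, i] = p
            pair_p.append(p)
            pairs.append((i, j))
            k += 1
    sig_flat = _bh_mask(np.asarray(pair_p), fdr_q)
    significant = np.zeros((n, n), dtype=bool)
    for (i, j), s in zip(pairs, sig_flat):
        significant[i, j] = significant[j, i] = bool(s)
    return D, P, significant
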
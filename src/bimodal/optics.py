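"""Optical characterization of a GRIN-lens imaging system.

Four measurements on calibration images, mirroring standard two-photon
system QC:

* **magnification** — the factor by which imaging through the relay-lens
  system changes pixels-per-micron, measured from the line period of a
  50-µm grid-slide image (autocorrelation of the mean line profile, with
  sub-pixel parabolic peak interpolation) relative to a reference scale;
* **field of view** — baseline-subtracted grid profile peaks above 10% of
  the maximum, counted and multiplied by the grid spacing;
* **lateral resolution** — mean FWHM of 1-D Gaussian fits to line
  profiles through five randomly sampled beads, corrected by 1/M;
* **axial resolution** — mean FWHM of Gaussian fits to the z-profiles
  through five beads' brightest voxels, corrected by 1/M².
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import ndimage, optimize, signal

from .containers import OpticsReport

__all__ = [
    "magnification_from_grid",
    "fov_from_grid",
    "lateral_fwhm",
    "axial_fwhm",
    "optics_report",
]

log = logging.getLogger(__name__)

_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


def _grid_profile(image):
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("grid image must be 2-D")
    return img.mean(axis=0)


def _grid_period_px(profile) -> float:
    """Line period from the autocorrelation of the mean profile, with
    parabolic sub-pixel interpolation of the first peak."""
    p = profile - profile.mean()
    ac = np.correlate(p, p, mode="full")[p.size - 1 :]
    if ac[0] <= 0:
        raise ValueError("flat profile: no periodic structure")
    peaks, _ = signal.find_peaks(ac[2:], height=0)
    peaks += 2
    # a genuine grid repeats most of the profile energy at the period;
    # random profiles put only O(1/sqrt(n)) of ac[0] into any lag
    noise_floor = 1.4826 * np.median(np.abs(ac[2:]))
    peaks = [
        k
        for k in peaks
        if ac[k] >= 3.0 * noise_floor and ac[k] >= 0.1 * ac[0]
    ]
    if not peaks:
        raise ValueError(
            "no periodic structure: autocorrelation peak below 3x noise floor"
        )
    k = int(peaks[0])
    if 0 < k < ac.size - 1:
        denom = ac[k - 1] - 2 * ac[k] + ac[k + 1]
        delta = 0.5 * (ac[k - 1] - ac[k + 1]) / denom if denom != 0 else 0.0
    else:
        delta = 0.0
    return k + float(delta)


def magnification_from_grid(
    image, reference_px_per_um: float, grid_spacing_um: float = 50.0
) -> float:
    """Magnification M of the imaging system from a grid-slide image.

    M = (measured px/µm through the system) / (reference px/µm without
    it). The measured scale comes from the grid line period.
    """
    if reference_px_per_um <= 0 or grid_spacing_um <= 0:
        raise ValueError("scales must be > 0")
    period = _grid_period_px(_grid_profile(image))
    measured_px_per_um = period / grid_spacing_um
    return measured_px_per_um / reference_px_per_um


def fov_from_grid(
    image,
    grid_spacing_um: float = 50.0,
    threshold_frac: float = 0.10,
    mode: str = "count",
) -> float:
    """Field of view from a grid-slide image.

    The mean line profile is baseline-subtracted (rolling minimum over
    one grid period, clamped at zero) and local maxima exceeding
    ``threshold_frac`` of the profile maximum are counted;
    FOV = count × grid spacing. ``mode="extent"`` instead returns the
    spacing-scaled distance between the extreme peaks plus one spacing.
    """
    profile = _grid_profile(image)
    try:
        period = _grid_period_px(profile)
    except ValueError:
        # a single line has no measurable period; use a frame-scale window
        period = profile.size / 2.0
    win = max(3, int(round(period)))
    baseline = ndimage.minimum_filter1d(profile, size=win, mode="nearest")
    prof = np.clip(profile - baseline, 0.0, None)
    height = threshold_frac * prof.max()
    peaks, _ = signal.find_peaks(
        prof, height=height, distance=max(1, int(period / 2))
    )
    if peaks.size == 0:
        raise ValueError("no grid peaks above threshold")
    if mode == "extent":
        if peaks.size < 2:
            return grid_spacing_um
        return (peaks[-1] - peaks[0]) / period * grid_spacing_um + grid_spacing_um
    return float(peaks.size) * grid_spacing_um


def _gauss(x, amp, center, sigma, offset):
    return amp * np.exp(-((x - center) ** 2) / (2 * sigma**2)) + offset


def _fit_fwhm_1d(profile, x=None):
    """FWHM (in samples, or x units) of a Gaussian fit to one profile."""
    y = np.asarray(profile, dtype=float)
    if x is None:
        x = np.arange(y.size, dtype=float)
    i0 = int(np.argmax(y))
    amp0 = y[i0] - y.min()
    half = y.min() + amp0 / 2.0
    above = y >= half
    sigma0 = max(1.0, above.sum() / _FWHM) * (x[1] - x[0])
    popt, _ = optimize.curve_fit(
        _gauss,
        x,
        y,
        p0=[amp0, x[i0], sigma0, y.min()],
        maxfev=10000,
    )
    return abs(popt[2]) * _FWHM, popt[1]


def _find_spots(image, min_distance, n_sd=5.0, min_contrast_frac=0.2):
    """Local maxima exceeding n_sd robust SDs above the median background
    and ``min_contrast_frac`` of the image's peak-to-background range (the
    latter rejects background extreme values, whose distribution is
    heavier-tailed than Gaussian in maximum projections)."""
    img = np.asarray(image, dtype=float)
    med = np.median(img)
    rsd = 1.4826 * np.median(np.abs(img - med))
    if rsd == 0:
        rsd = img.std() / 5.0 or 1e-12
    footprint = np.ones((min_distance,) * img.ndim, dtype=bool)
    local_max = img == ndimage.maximum_filter(img, footprint=footprint)
    thr = med + max(n_sd * rsd, min_contrast_frac * (img.max() - med))
    mask = local_max & (img > thr)
    return np.argwhere(mask)


def lateral_fwhm(
    bead_image,
    magnification: float,
    px_per_um: float,
    n_beads: int = 5,
    seed: int = 0,
    profile_halfwidth_px: int = 20,
) -> tuple[float, np.ndarray]:
    """Magnification-corrected lateral FWHM (µm) from a bead image.

    ``n_beads`` beads are sampled at random (seeded, without replacement)
    from detected bright spots; each contributes the FWHM of a 1-D
    Gaussian fit to the horizontal line profile through its center. The
    mean FWHM is divided by the pixel scale and multiplied by 1/M.
    Returns ``(mean_corrected_fwhm_um, per_bead_fwhm_um)``.
    """
    img = np.asarray(bead_image, dtype=float)
    spots = _find_spots(img, min_distance=max(3, profile_halfwidth_px // 2))
    if len(spots) < n_beads:
        raise ValueError(
            f"found only {len(spots)} candidate beads, need {n_beads}"
        )
    rng = np.random.default_rng(seed)
    chosen = spots[rng.choice(len(spots), size=n_beads, replace=False)]
    fwhms = []
    for cy, cx in chosen:
        lo = max(0, cx - profile_halfwidth_px)
        hi = min(img.shape[1], cx + profile_halfwidth_px + 1)
        fwhm_px, _ = _fit_fwhm_1d(img[cy, lo:hi])
        fwhms.append(fwhm_px / px_per_um)
    per_bead = np.asarray(fwhms)
    return float(per_bead.mean() / magnification), per_bead / magnification


def axial_fwhm(
    bead_stack,
    magnification: float,
    z_step_um: float,
    n_beads: int = 5,
    seed: int = 0,
    xy_min_distance_px: int = 9,
) -> tuple[float, np.ndarray]:
    """Magnification-corrected axial FWHM (µm) from a bead z-stack.

    Gaussian fits to the z-profiles through each sampled bead's brightest
    voxel; the mean FWHM (in µm, via ``z_step_um``) is multiplied by
    1/M². Beads whose fitted axial profile is truncated by the stack
    boundary are skipped with a warning. Returns
    ``(mean_corrected_fwhm_um, per_bead_fwhm_um)``.
    """
    stack = np.asarray(bead_stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("bead stack must be 3-D (z, y, x)")
    proj = stack.max(axis=0)
    spots = _find_spots(proj, min_distance=xy_min_distance_px)
    if len(spots) < n_beads:
        raise ValueError(
            f"found only {len(spots)} candidate beads, need {n_beads}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(spots))
    fwhms = []
    nz = stack.shape[0]
    for k in order:
        if len(fwhms) >= n_beads:
            break
        cy, cx = spots[k]
        zprof = stack[:, cy, cx]
        fwhm_sl, center = _fit_fwhm_1d(zprof)
        sigma_sl = fwhm_sl / _FWHM
        if center - 2 * sigma_sl < 0 or center + 2 * sigma_sl > nz - 1:
            log.warning(
                "skipping bead at (y=%d, x=%d): axial profile truncated by "
                "the stack boundary",
                cy,
                cx,
            )
            continue
        fwhms.append(fwhm_sl * z_step_um)
    if len(fwhms) < n_beads:
        raise ValueError(
            f"only {len(fwhms)} untruncated beads available, need {n_beads}"
        )
    per_bead = np.asarray(fwhms)
    return float(per_bead.mean() / magnification**2), per_bead / magnification**2


def optics_report(
    grid_image,
    bead_image,
    bead_stack,
    reference_px_per_um: float,
    z_step_um: float,
    grid_spacing_um: float = 50.0,
    n_beads: int = 5,
    seed: int = 0,
) -> OpticsReport:
    """Run the full optical characterization of one imaging system."""
    m = magnification_from_grid(
        grid_image, reference_px_per_um, grid_spacing_um
    )
    fov = fov_from_grid(grid_image, grid_spacing_um)
    lat, lat_beads = lateral_fwhm(
        bead_image,
        magnification=m,
        px_per_um=reference_px_per_um,
        n_beads=n_beads,
        seed=seed,
    )
    ax, ax_beads = axial_fwhm(
        bead_stack,
        magnification=m,
        z_step_um=z_step_um,
        n_beads=n_beads,
        seed=seed,
    )
    return OpticsReport(
        magnification=m,
        fov_um=fov,
        lateral_fwhm_um=lat,
        axial_fwhm_um=ax,
        n_beads_used=n_beads,
        per_bead_lateral_um=lat_beads,
        per_bead_axial_um=ax_beads,
    )
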
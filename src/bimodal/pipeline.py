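"""End-to-end session analysis: simulate/load → band power → correlations
→ spike matching → spatial maps → summary bundle.

``run_all`` writes, into an output directory: ``corr.h5`` (ρ, p, masks),
``match.json`` (per-unit ROI rankings), ``maps.h5`` (spatial maps and
pairwise tests, when a track is present), ``summary.json`` (per-band ρ
histogram moments, KS statistics, significant fractions, best spike
match, map verdicts) and ``run.log``. Re-running with the same config
yields a byte-identical ``summary.json``.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from . import session_io, spatial, spikes as spk, synthetic
from .containers import CANONICAL_BANDS
from .correlate import correlate_session, top_correlated_rois
from .lfp import band_power_traces

__all__ = ["RunConfig", "run_all", "make_demo", "DEMO_PRESETS"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one end-to-end analysis run."""

    session_path: str | None = None
    session_config: synthetic.SessionConfig | None = None
    out_dir: str = "bimodal_out"
    n_shuffles: int = 100
    min_shift_frac: float = 0.1
    fdr_q: float = 0.05
    decay_tau_s: float = 0.7
    bin_px: float = 25.0
    sigma_px: float = 62.5
    n_resample: int = 500
    map_rois: int = 6
    transient_threshold_sd: float = 3.0
    seed: int = 0
    pool_bands: bool = False

    def __post_init__(self):
        if (self.session_path is None) == (self.session_config is None):
            raise ValueError(
                "exactly one of session_path or session_config is required"
            )


DEMO_PRESETS = ("headfixed_100roi", "freelymoving_place", "null")


def make_demo(preset: str, out_dir, seed: int = 0, force: bool = False) -> Path:
    """Write a ready-to-analyze synthetic session directory.

    Presets: ``headfixed_100roi`` (100 ROIs, 16 electrodes, 10 min, half
    the ROIs theta-coupled at weight 0.5), ``freelymoving_place`` (8-min
    arena session at 30 fps video with place-modulated ROIs) and ``null``
    (zero coupling control at head-fixed scale).
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(
            f"{out_dir} exists and is not empty; pass force=True to overwrite"
        )
    cfg = demo_config(preset, seed)
    traces, rec, spikes, track, truth = synthetic.generate_session(cfg)
    truth_json = {
        "coupling_matrix": truth.coupling_matrix.tolist(),
        "place_field_centers": (
            None
            if truth.place_field_centers is None
            else truth.place_field_centers.tolist()
        ),
        "latent_freqs_hz": list(truth.latent_freqs_hz),
        "band_names": list(truth.band_names),
        "n_spikes": {str(k): int(v.size) for k, v in truth.spike_times.items()},
        "seed": cfg.seed,
        "preset": preset,
    }
    keep_track = preset == "freelymoving_place"
    session_io.save_session(
        out_dir,
        traces,
        rec,
        spikes=spikes,
        track=track if keep_track else None,
        truth=truth_json,
    )
    return out_dir


def demo_config(preset: str, seed: int = 0) -> synthetic.SessionConfig:
    if preset == "headfixed_100roi":
        return synthetic.coupled_config(
            coupled_fraction=0.5,
            weight=0.5,
            band=0,
            n_rois=100,
            n_electrodes=16,
            duration_s=600.0,
            seed=seed,
        )
    if preset == "null":
        return synthetic.SessionConfig(
            n_rois=100, n_electrodes=16, duration_s=600.0, seed=seed
        )
    if preset == "freelymoving_place":
        n_rois = 8
        rng = np.random.default_rng(seed)
        centers = rng.uniform(60, 440, size=(n_rois, 2))
        coupling = np.zeros((n_rois, 4))
        coupling[: n_rois // 2, 0] = 0.5
        return synthetic.SessionConfig(
            n_rois=n_rois,
            n_electrodes=16,
            duration_s=480.0,
            video_rate_hz=30.0,
            coupling_matrix=coupling,
            place_field_centers=centers,
            baseline_rate_hz=2.0,
            seed=seed,
        )
    raise ValueError(f"unknown preset {preset!r}; choose from {DEMO_PRESETS}")


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_all(config: RunConfig) -> dict:
    """Run the full analysis described in the module docstring.

    Returns the summary dictionary (also written to ``summary.json``).
    Any stage failure raises with the stage named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logfile = out / "run.log"
    handler = logging.FileHandler(logfile, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    runlog = logging.getLogger("bimodal.run")
    runlog.setLevel(logging.INFO)
    runlog.addHandler(handler)
    summary: dict = {"config": {
        "n_shuffles": config.n_shuffles,
        "min_shift_frac": config.min_shift_frac,
        "fdr_q": config.fdr_q,
        "decay_tau_s": config.decay_tau_s,
        "bin_px": config.bin_px,
        "sigma_px": config.sigma_px,
        "n_resample": config.n_resample,
        "seed": config.seed,
    }}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                runlog.error("stage %s FAILED: %s", name, exc)
                handler.close()
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            runlog.info("stage %s done in %.2f s", name, time.perf_counter() - t0)
            return result

        return wrap

    # -- load / simulate ---------------------------------------------------
    if config.session_path is not None:
        traces, rec, spikes, track = stage("load")(
            lambda: session_io.load_session(config.session_path)
        )
    else:
        traces, rec, spikes, track, _ = stage("simulate")(
            lambda: synthetic.generate_session(config.session_config)
        )

    # -- band power --------------------------------------------------------
    bp = stage("band_power")(
        lambda: band_power_traces(rec, traces.frame_times_s, CANONICAL_BANDS)
    )

    # -- correlations ------------------------------------------------------
    corr = stage("correlate")(
        lambda: correlate_session(
            traces,
            bp,
            n_shuffles=config.n_shuffles,
            min_shift_frac=config.min_shift_frac,
            fdr_q=config.fdr_q,
            seed=config.seed,
            pool_bands=config.pool_bands,
        )
    )
    with h5py.File(out / "corr.h5", "w") as f:
        f.create_dataset("rho", data=corr.rho)
        f.create_dataset("p_emp", data=corr.p_emp)
        f.create_dataset("significant", data=corr.significant)
        f.create_dataset("null_rho", data=corr.null_rho, compression="gzip")
        f.attrs["band_names"] = corr.band_names
        f.attrs["fdr_q"] = corr.fdr_q
    band_summary = {}
    for b, name in enumerate(corr.band_names):
        r = corr.rho[:, :, b]
        r = r[np.isfinite(r)]
        nul = corr.null_rho[:, :, b, :]
        nul = nul[np.isfinite(nul)]
        band_summary[name] = {
            "rho_mean": float(r.mean()),
            "rho_median": float(np.median(r)),
            "rho_sd": float(r.std()),
            "shuffled_rho_mean": float(nul.mean()),
            "ks_stat": float(corr.ks_stat[b]),
            "ks_p": float(corr.ks_p[b]),
            "fraction_significant": float(corr.fraction_significant[b]),
            "fraction_significant_shuffled": float(
                corr.fraction_significant_shuffled[b]
            ),
            "top_rois": top_correlated_rois(corr, name, k=4),
        }
    summary["bands"] = band_summary
    summary["n_constant_rois"] = corr.n_constant_rois

    # -- spike matching ----------------------------------------------------
    if spikes is not None and len(spikes):
        def do_match():
            results = []
            for u in spikes:
                if u.spike_times_s.size == 0:
                    continue
                pseudo = spk.convolve_spikes(
                    u, config.decay_tau_s, traces.frame_times_s
                )
                if np.std(pseudo.values) == 0:
                    continue
                m = spk.best_match(pseudo, traces)
                results.append(
                    {
                        "unit_id": int(m.unit_id),
                        "best_roi": int(m.best_roi),
                        "best_rho": float(m.best_rho),
                        "ranking": m.ranking[:10],
                    }
                )
            return results

        matches = stage("spike_match")(do_match)
        (out / "match.json").write_text(
            json.dumps(_round_floats(matches), indent=1, sort_keys=True)
        )
        if matches:
            best = max(matches, key=lambda m: m["best_rho"])
            summary["best_spike_match"] = {
                "unit_id": best["unit_id"],
                "roi_id": best["best_roi"],
                "rho": best["best_rho"],
            }

    # -- spatial maps ------------------------------------------------------
    if track is not None:
        def do_maps():
            arena = (
                config.session_config.arena_px
                if config.session_config is not None
                else (
                    float(np.ceil(track.xy_px[:, 0].max())),
                    float(np.ceil(track.xy_px[:, 1].max())),
                )
            )
            ids = list(traces.roi_ids[: config.map_rois])
            maps = [
                spatial.build_spatial_map(
                    traces.dff[list(traces.roi_ids).index(i)],
                    traces.frame_times_s,
                    track,
                    arena,
                    bin_px=config.bin_px,
                    sigma_px=config.sigma_px,
                )
                for i in ids
            ]
            D, P, sig = spatial.pairwise_map_tests(
                maps,
                n_resample=config.n_resample,
                seed=config.seed,
                fdr_q=config.fdr_q,
            )
            vel = spatial.head_velocity(track)
            with h5py.File(out / "maps.h5", "w") as f:
                for i, m in zip(ids, maps):
                    g = f.create_group(f"roi_{i}")
                    g.create_dataset("occupancy_s", data=m.occupancy_s)
                    g.create_dataset("normalized", data=m.normalized)
                f.create_dataset("ks2d_D", data=D)
                f.create_dataset("ks2d_p", data=P)
                f.create_dataset("significant", data=sig)
                f.create_dataset("velocity_px_s", data=vel)
            n_pairs = sig.shape[0] * (sig.shape[0] - 1) // 2
            return {
                "roi_ids": [int(i) for i in ids],
                "n_pairs": int(n_pairs),
                "n_significant_pairs": int(sig.sum() // 2),
                "median_velocity_px_s": float(np.median(vel)),
            }

        summary["maps"] = stage("spatial_maps")(do_maps)

    text = json.dumps(_round_floats(summary), indent=1, sort_keys=True)
    (out / "summary.json").write_text(text)
    runlog.info("summary written to %s", out / "summary.json")
    runlog.removeHandler(handler)
    handler.close()
    return summary
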
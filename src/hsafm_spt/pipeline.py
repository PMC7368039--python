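"""End-to-end runs and report generation.

``run_pipeline`` chains simulate → drift-correct → detect → link → MSD/fit
→ tilt/rotation → ensemble summary, writing one CSV/JSON artefact per stage
plus a manifest (config hash, seed, package version, stage outputs) so any
output can be regenerated from the manifest alone.  ``make_report``
tabulates per-composition ensembles and the composition trend.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import read_stack
from .simulate import SimConfig, simulate_trajectories, render_movie, write_fixture
from .tracking import (
    LinkingParams,
    correct_drift,
    default_max_step_nm,
    detect_movie,
    link_detections,
    write_tracks_csv,
)
from .diffusion import (
    TrackTooShortError,
    compute_msd,
    composition_trend,
    fit_brownian,
    fit_directed,
    fit_lognormal,
)
from .tilt import estimate_length, orientation_trace, rotation_steps, tilt_histogram, tilt_trace

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "make_report"]

log = logging.getLogger("hsafm_spt")

_SCHEMA = {
    "schema_version": int,
    "seed": int,
    "composition_label": str,
    "dmpc_fraction": (int, float, type(None)),
    "simulate": dict,
    "tracking": dict,
    "analysis": dict,
    "tilt": dict,
}
_TRACKING_KEYS = {"min_height_nm", "sigma_range_nm", "max_step_nm",
                  "max_gap_frames", "min_track_length", "drift_correct"}
_ANALYSIS_KEYS = {"model", "fit_intercept", "weights"}
_TILT_KEYS = {"bin_width_deg", "window_px", "min_asymmetry",
              "rotation_bin_width_deg", "length_quantile"}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and its context."""


class RunConfig:
    """Validated JSON run configuration (unknown keys rejected)."""

    def __init__(self, raw: dict):
        unknown = set(raw) - set(_SCHEMA)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key, typ in _SCHEMA.items():
            if key in raw and not isinstance(raw[key], typ):
                raise ValueError(f"config key {key!r} has wrong type")
        for section, allowed in (("tracking", _TRACKING_KEYS),
                                 ("analysis", _ANALYSIS_KEYS),
                                 ("tilt", _TILT_KEYS)):
            bad = set(raw.get(section, {})) - allowed
            if bad:
                raise ValueError(f"unknown {section} key(s): {sorted(bad)}")
        self.raw = {
            "schema_version": 1,
            "seed": 0,
            "composition_label": "",
            "dmpc_fraction": None,
            "simulate": {},
            "tracking": {},
            "analysis": {},
            "tilt": {},
            **raw,
        }

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(json.loads(Path(path).read_text()))

    def sim_config(self) -> SimConfig:
        sim = dict(self.raw["simulate"])
        sim.setdefault("seed", self.raw["seed"])
        return SimConfig.from_dict(sim)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.2f s", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


def run_pipeline(config: RunConfig | dict, out_dir: str | Path,
                 movie_path: str | Path | None = None) -> dict:
    """Execute the full analysis and write per-stage artefacts.

    With no ``movie_path`` a synthetic movie is generated from the config's
    ``simulate`` section (and its ground truth saved); otherwise the given
    calibrated TIFF is analysed.  Returns the manifest dict, also written to
    ``manifest.json``.  Identical config + seed give identical outputs.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    # -- simulate (or load) ------------------------------------------------
    if movie_path is None:
        def _simulate():
            sim_cfg = config.sim_config()
            truth = simulate_trajectories(sim_cfg)
            return truth, render_movie(truth, sim_cfg), sim_cfg

        truth, stack, sim_cfg = _stage("simulate")(_simulate)()
        paths = write_fixture(truth, stack, sim_cfg, out)
        outputs["simulate"] = Path(paths["movie"]).name
    else:
        stack = _stage("load")(read_stack)(movie_path)
        outputs["load"] = str(movie_path)

    trk = config.raw["tracking"]
    # -- drift correction --------------------------------------------------
    if trk.get("drift_correct", True):
        stack, shifts = _stage("drift_correct")(correct_drift)(stack)
    else:
        shifts = np.zeros((stack.n_frames, 2))
    shifts_df = pd.DataFrame(shifts, columns=["shift_row_px", "shift_col_px"])
    shifts_df.insert(0, "frame", np.arange(stack.n_frames))
    shifts_df.to_csv(out / "drift_shifts.csv", index=False)
    outputs["drift_correct"] = "drift_shifts.csv"

    # -- detection ---------------------------------------------------------
    det_kwargs = {}
    if "min_height_nm" in trk:
        det_kwargs["min_height_nm"] = trk["min_height_nm"]
    if "sigma_range_nm" in trk:
        det_kwargs["sigma_range_nm"] = tuple(trk["sigma_range_nm"])
    detections = _stage("detect")(detect_movie)(stack, **det_kwargs)

    # -- linking -----------------------------------------------------------
    link_params = LinkingParams(
        max_step_nm=trk.get("max_step_nm",
                            default_max_step_nm(stack.frame_interval_s)),
        max_gap_frames=trk.get("max_gap_frames", 2),
        min_track_length=trk.get("min_track_length", 10),
    )
    tracks = _stage("link")(link_detections)(detections, link_params)
    write_tracks_csv(tracks, out / "tracks.csv")
    outputs["link"] = "tracks.csv"
    if not tracks:
        raise PipelineError("stage 'link' failed: no trajectories survived linking")

    # -- MSD + diffusion fits ----------------------------------------------
    ana = config.raw["analysis"]
    model = ana.get("model", "brownian")
    fit_fn = {"brownian": fit_brownian, "directed": fit_directed}[model]
    fit_kwargs = {k: ana[k] for k in ("fit_intercept", "weights") if k in ana}
    rows, msd_rows = [], []
    for tr in tracks:
        try:
            curve = compute_msd(tr, stack.frame_interval_s)
            est = fit_fn(curve, **fit_kwargs)
        except TrackTooShortError:
            continue
        rows.append({
            "track_id": tr.particle_id,
            "n_points": len(tr),
            "D_um2_s": est.D_um2_s,
            "v_nm_s": est.v_nm_s if est.v_nm_s is not None else np.nan,
            "intercept_nm2": est.intercept_nm2,
            "r2": est.r2,
            "model": est.model,
        })
        for lag, msd, n in zip(curve.lag_s, curve.msd_nm2, curve.n_pairs):
            msd_rows.append({"track_id": tr.particle_id, "lag_s": lag,
                             "msd_nm2": msd, "n_pairs": n})
    if not rows:
        raise PipelineError("stage 'msd_fit' failed: no track long enough to fit")
    diff_df = pd.DataFrame(rows)
    diff_df.to_csv(out / "diffusion.csv", index=False)
    pd.DataFrame(msd_rows).to_csv(out / "msd_curves.csv", index=False)
    outputs["msd_fit"] = "diffusion.csv"

    # -- tilt + rotation ---------------------------------------------------
    tl = config.raw["tilt"]
    tilt_rows, hist_rows, rot_summaries = [], [], []
    for tr in tracks:
        heights = tr.heights_nm
        if not np.any(np.isfinite(heights) & (heights > 0)):
            continue
        params = estimate_length(heights, quantile=tl.get("length_quantile"))
        trace = tilt_trace(tr, params, stack.frame_interval_s)
        for t, th, cl in zip(trace.time_s, trace.theta_deg, trace.clamped):
            tilt_rows.append({"track_id": tr.particle_id, "time_s": t,
                              "theta_deg": th, "clamped": bool(cl)})
        edges, counts = tilt_histogram(trace, tl.get("bin_width_deg", 2.5))
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            if c:
                hist_rows.append({"track_id": tr.particle_id, "theta_lo_deg": lo,
                                  "theta_hi_deg": hi, "count": int(c)})
        otrace = orientation_trace(
            stack, tr, window_px=tl.get("window_px", 7),
            min_asymmetry=tl.get("min_asymmetry", 1.15),
        )
        try:
            hist = rotation_steps(
                otrace, bin_width_deg=tl.get("rotation_bin_width_deg", 10.0))
            rot_summaries.append({
                "track_id": tr.particle_id,
                "n_steps": hist.n_steps,
                "gaussian_mu_deg": hist.gaussian_mu_deg,
                "gaussian_sigma_deg": hist.gaussian_sigma_deg,
                "mle_mu_deg": hist.mle_mu_deg,
                "mle_sigma_deg": hist.mle_sigma_deg,
            })
        except ValueError:
            pass
    pd.DataFrame(tilt_rows).to_csv(out / "tilt_trace.csv", index=False)
    pd.DataFrame(hist_rows).to_csv(out / "tilt_histogram.csv", index=False)
    (out / "rotation_steps.json").write_text(json.dumps(rot_summaries, indent=2))
    outputs["tilt_rotation"] = "tilt_trace.csv"

    # -- ensemble summary --------------------------------------------------
    summary: dict = {
        "composition_label": config.raw["composition_label"],
        "dmpc_fraction": config.raw["dmpc_fraction"],
        "n_tracks": int(len(diff_df)),
        "model": model,
    }
    D = diff_df["D_um2_s"].to_numpy()
    try:
        stats = fit_lognormal(D, composition_label=summary["composition_label"],
                              dmpc_fraction=summary["dmpc_fraction"])
        summary.update(
            mean_D_um2_s=stats.arithmetic_mean_D,
            geometric_mean_D_um2_s=stats.geometric_mean_D,
            mu_log=stats.mu_log,
            sigma_log=stats.sigma_log,
            n_excluded=stats.n_excluded,
        )
    except ValueError:
        summary.update(mean_D_um2_s=float(np.mean(D[D > 0])) if (D > 0).any()
                       else None)
    (out / "ensemble.json").write_text(json.dumps(summary, indent=2))
    outputs["ensemble"] = "ensemble.json"

    manifest = {
        "package": "hsafm-spt",
        "version": __version__,
        "config": config.raw,
        "config_hash": config.hash(),
        "seed": config.raw["seed"],
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def make_report(run_dirs: list) -> dict:
    """Per-composition summary table + composition trend over finished runs.

    Reads each run's ``ensemble.json``; rows are ordered by DMPC fraction.
    Returns ``{"table": DataFrame-ready records, "trend": trend report}``.
    """
    summaries = []
    for d in run_dirs:
        p = Path(d) / "ensemble.json"
        if not p.exists():
            raise FileNotFoundError(f"no ensemble.json in {d!r} — run the analysis first")
        summaries.append(json.loads(p.read_text()))
    if not summaries:
        raise ValueError("no analysis directories given")
    summaries.sort(key=lambda s: (s.get("dmpc_fraction") is None,
                                  s.get("dmpc_fraction", 0)))
    table = [
        {
            "composition": s.get("composition_label", ""),
            "dmpc_fraction": s.get("dmpc_fraction"),
            "n_tracks": s.get("n_tracks"),
            "mean_D_um2_s": s.get("mean_D_um2_s"),
            "mu_log": s.get("mu_log"),
            "sigma_log": s.get("sigma_log"),
        }
        for s in summaries
    ]
    with_frac = [s for s in summaries if s.get("dmpc_fraction") is not None
                 and "mu_log" in s]
    if len(with_frac) >= 2:
        from .diffusion import EnsembleStats

        ens = [
            EnsembleStats(
                composition_label=s["composition_label"],
                D_um2_s=np.array([s["mean_D_um2_s"]]),
                mu_log=s["mu_log"], sigma_log=s["sigma_log"],
                arithmetic_mean_D=s["mean_D_um2_s"],
                geometric_mean_D=s["geometric_mean_D_um2_s"],
                dmpc_fraction=s["dmpc_fraction"],
            )
            for s in with_frac
        ]
        trend = composition_trend(ens)
        # n_tracks in the trend report should reflect the real ensemble sizes
        trend["n_tracks"] = [s["n_tracks"] for s in with_frac]
    else:
        trend = {"verdict": "none", "spearman_rho": None}
    return {"table": table, "trend": trend}
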
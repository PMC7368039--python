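"""Ground-truthed synthetic HS-AFM movies of membrane inclusions.

Generates Brownian (optionally drifting) in-plane trajectories of nanotube
porins in a supported bilayer, a mean-reverting tilt-angle process, angular
Brownian motion of the in-plane azimuth, and renders each particle as a
height "bump" whose peak equals ``L·cosθ − T_b − T_w`` — the rigid-rod
geometry relating porin tilt to apparent AFM height.  Defaults emulate the
imaging regime the analysis targets: 128×128-pixel frames over a 200×200 nm
field at 0.2–0.5 s per frame, ~2.9 nm-high bumps, D of 1e-4–1e-3 µm²/s and
tilts in 0–25°.

Everything is reproducible from a single master seed; per-particle and
per-noise random streams are spawned deterministically from it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import ImageStack, read_stack, write_stack

__all__ = [
    "TiltDynamics",
    "BumpModel",
    "SimConfig",
    "GroundTruth",
    "simulate_trajectories",
    "render_movie",
    "simulate_movie",
    "write_fixture",
    "read_fixture",
]

NM2_PER_UM2 = 1.0e6

TRUTH_COLUMNS = ["particle_id", "frame", "x_nm", "y_nm", "theta_deg", "phi_deg", "h_nm"]


@dataclass
class TiltDynamics:
    """Bounded mean-reverting tilt fluctuations.

    The tilt angle follows an Ornstein–Uhlenbeck process reflected into
    ``[theta_min_deg, theta_max_deg]``; the OU mean sits at the interval
    midpoint.  ``theta_sd_deg`` is the stationary spread of the unreflected
    process and ``relaxation_time_s`` its correlation time.
    """

    theta_min_deg: float = 0.0
    theta_max_deg: float = 25.0
    relaxation_time_s: float = 2.0
    theta_sd_deg: float = 5.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_min_deg <= self.theta_max_deg < 90.0):
            raise ValueError("require 0 <= theta_min <= theta_max < 90 deg")
        if self.relaxation_time_s <= 0 or self.theta_sd_deg < 0:
            raise ValueError("relaxation_time_s > 0 and theta_sd_deg >= 0 required")


@dataclass
class BumpModel:
    """How a tilted rod appears as a surface bump.

    ``gaussian`` renders an anisotropic Gaussian of amplitude
    ``L·cosθ − T_b − T_w`` elongated along the azimuth (fast; default).
    ``cylinder_dilation`` builds the tilted-capsule height field and dilates
    it with a spherical tip of ``tip_radius_nm`` — the standard tip-sample
    dilation model of AFM imaging (slower, for realism checks).
    """

    renderer: str = "gaussian"
    cnt_length_nm: float = 8.0
    cnt_radius_nm: float = 0.75
    bilayer_thickness_nm: float = 4.1
    water_layer_nm: float = 1.0
    tip_radius_nm: float = 5.0
    gaussian_sigma_nm: float = 2.5
    aspect_gain: float = 0.02  # fractional major-axis elongation per degree of tilt

    def __post_init__(self) -> None:
        if self.renderer not in ("gaussian", "cylinder_dilation"):
            raise ValueError(f"unknown renderer {self.renderer!r}")
        if not self.tip_radius_nm < 10.0:
            raise ValueError("tip_radius_nm must be < 10 nm")
        if not self.cnt_length_nm > self.bilayer_thickness_nm + self.water_layer_nm:
            raise ValueError("rod length must exceed T_b + T_w (no protrusion otherwise)")

    def peak_height_nm(self, theta_deg) -> np.ndarray:
        """Apparent height h(θ) = L·cosθ − T_b − T_w of the protruding tip."""
        theta = np.deg2rad(np.asarray(theta_deg, dtype=float))
        return (
            self.cnt_length_nm * np.cos(theta)
            - self.bilayer_thickness_nm
            - self.water_layer_nm
        )


@dataclass
class SimConfig:
    """Full description of a synthetic movie.

    ``D_true_um2_s`` may be a scalar (shared by all particles) or a sequence
    of per-particle diffusion coefficients in µm²/s.
    """

    field_size_nm: float = 200.0
    n_pixels: int = 128
    frame_interval_s: float = 0.5
    n_frames: int = 100
    n_particles: int = 1
    D_true_um2_s: float | tuple = 5.0e-4
    drift_velocity_nm_s: tuple = (0.0, 0.0)
    tilt_params: TiltDynamics = field(default_factory=TiltDynamics)
    orientation_D_deg2_s: float = 20.0
    bump: BumpModel = field(default_factory=BumpModel)
    noise_sd_nm: float = 0.29
    seed: int = 0
    global_drift_nm_per_frame: tuple = (0.0, 0.0)  # scanner drift applied at render
    raster_line_skew: bool = False  # reserved; frames are instantaneous

    def __post_init__(self) -> None:
        if self.field_size_nm <= 0:
            raise ValueError("field_size_nm must be positive")
        if self.n_pixels < 16:
            raise ValueError("n_pixels must be >= 16")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        D = np.atleast_1d(np.asarray(self.D_true_um2_s, dtype=float))
        if not np.all(np.isfinite(D)) or np.any(D < 0):
            raise ValueError("D_true_um2_s must be finite and >= 0")
        if self.noise_sd_nm < 0:
            raise ValueError("noise_sd_nm must be >= 0")
        if self.raster_line_skew:
            raise NotImplementedError("raster-line skew is reserved for future use")

    @property
    def nm_per_pixel(self) -> float:
        return self.field_size_nm / self.n_pixels

    def D_per_particle_nm2_s(self) -> np.ndarray:
        D = np.atleast_1d(np.asarray(self.D_true_um2_s, dtype=float))
        if D.size == 1:
            D = np.repeat(D, self.n_particles)
        if D.size != self.n_particles:
            raise ValueError("D_true_um2_s must be scalar or one value per particle")
        return D * NM2_PER_UM2

    def to_dict(self) -> dict:
        d = asdict(self)
        d["D_true_um2_s"] = (
            list(np.atleast_1d(self.D_true_um2_s).astype(float))
            if np.ndim(self.D_true_um2_s)
            else float(self.D_true_um2_s)
        )
        d["drift_velocity_nm_s"] = list(d["drift_velocity_nm_s"])
        d["global_drift_nm_per_frame"] = list(d["global_drift_nm_per_frame"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "tilt_params" in d and isinstance(d["tilt_params"], dict):
            d["tilt_params"] = TiltDynamics(**d["tilt_params"])
        if "bump" in d and isinstance(d["bump"], dict):
            d["bump"] = BumpModel(**d["bump"])
        for key in ("drift_velocity_nm_s", "global_drift_nm_per_frame"):
            if key in d:
                d[key] = tuple(d[key])
        if isinstance(d.get("D_true_um2_s"), list):
            d["D_true_um2_s"] = tuple(d["D_true_um2_s"])
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-particle time series of position, tilt, azimuth and true height.

    Arrays have shape ``(n_particles, n_frames)``.  Azimuth is stored modulo
    180° because an unsigned rod has two-fold image symmetry.
    """

    x_nm: np.ndarray
    y_nm: np.ndarray
    theta_deg: np.ndarray
    phi_deg: np.ndarray
    h_nm: np.ndarray
    frame_interval_s: float

    @property
    def n_particles(self) -> int:
        return self.x_nm.shape[0]

    @property
    def n_frames(self) -> int:
        return self.x_nm.shape[1]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    def to_frame(self) -> pd.DataFrame:
        pid, fr = np.meshgrid(
            np.arange(self.n_particles), np.arange(self.n_frames), indexing="ij"
        )
        return pd.DataFrame(
            {
                "particle_id": pid.ravel(),
                "frame": fr.ravel(),
                "x_nm": self.x_nm.ravel(),
                "y_nm": self.y_nm.ravel(),
                "theta_deg": self.theta_deg.ravel(),
                "phi_deg": self.phi_deg.ravel(),
                "h_nm": self.h_nm.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, frame_interval_s: float) -> "GroundTruth":
        df = df.sort_values(["particle_id", "frame"])
        n_p = df["particle_id"].nunique()
        n_f = df["frame"].nunique()
        shape = (n_p, n_f)
        return cls(
            *(df[c].to_numpy(dtype=float).reshape(shape)
              for c in ("x_nm", "y_nm", "theta_deg", "phi_deg", "h_nm")),
            frame_interval_s=frame_interval_s,
        )


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold values into [lo, hi] by specular reflection at both walls."""
    if hi < lo:
        raise ValueError("reflection interval must have hi >= lo")
    if hi == lo:
        return np.full_like(np.asarray(x, dtype=float), lo)
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    return lo + span - np.abs(y - span)


def simulate_trajectories(config: SimConfig) -> GroundTruth:
    """Draw ground-truth particle kinematics for one movie.

    Positions take independent Gaussian steps of per-axis variance
    ``2·D·Δt`` plus ``drift·Δt``, reflected at the field edges.  Tilt follows
    a reflected Ornstein–Uhlenbeck process inside its bounds; the azimuth
    performs angular Brownian motion with diffusivity
    ``orientation_D_deg2_s``.
    """
    n_p, n_f = config.n_particles, config.n_frames
    dt = config.frame_interval_s
    D_nm2 = config.D_per_particle_nm2_s()
    drift = np.asarray(config.drift_velocity_nm_s, dtype=float)
    tp = config.tilt_params
    L = config.bump.cnt_length_nm
    Tb, Tw = config.bump.bilayer_thickness_nm, config.bump.water_layer_nm

    # one child stream per particle + one reserved for pixel noise at render
    streams = np.random.SeedSequence(config.seed).spawn(n_p + 1)

    x = np.empty((n_p, n_f))
    y = np.empty((n_p, n_f))
    theta = np.empty((n_p, n_f))
    phi = np.empty((n_p, n_f))

    # keep initial positions away from the edge so bumps render fully in-field
    margin = min(0.15 * config.field_size_nm, 4.0 * config.bump.gaussian_sigma_nm + 5.0)
    mid = 0.5 * (tp.theta_min_deg + tp.theta_max_deg)
    alpha = math.exp(-dt / tp.relaxation_time_s)
    ou_step_sd = tp.theta_sd_deg * math.sqrt(max(0.0, 1.0 - alpha * alpha))

    for p in range(n_p):
        rng = np.random.default_rng(streams[p])
        step_sd = math.sqrt(2.0 * D_nm2[p] * dt)
        x0 = rng.uniform(margin, config.field_size_nm - margin)
        y0 = rng.uniform(margin, config.field_size_nm - margin)
        steps = rng.normal(0.0, step_sd, size=(n_f - 1, 2)) + drift * dt
        xy = np.vstack([[x0, y0], steps]).cumsum(axis=0)
        x[p] = _reflect(xy[:, 0], 0.0, config.field_size_nm)
        y[p] = _reflect(xy[:, 1], 0.0, config.field_size_nm)

        th = np.empty(n_f)
        th[0] = _reflect(
            np.array(rng.normal(mid, tp.theta_sd_deg)), tp.theta_min_deg, tp.theta_max_deg
        ) if tp.theta_sd_deg > 0 else mid
        innov = rng.normal(0.0, 1.0, size=n_f - 1)
        for i in range(1, n_f):
            raw = mid + (th[i - 1] - mid) * alpha + ou_step_sd * innov[i - 1]
            th[i] = _reflect(np.array(raw), tp.theta_min_deg, tp.theta_max_deg)
        theta[p] = th

        phi0 = rng.uniform(0.0, 180.0)
        dphi = rng.normal(0.0, math.sqrt(2.0 * config.orientation_D_deg2_s * dt),
                          size=n_f - 1)
        phi[p] = np.mod(np.concatenate([[phi0], dphi]).cumsum(), 180.0)

    h = L * np.cos(np.deg2rad(theta)) - Tb - Tw
    return GroundTruth(x, y, theta, phi, h, frame_interval_s=dt)


def _render_gaussian_frame(img, x, y, theta, phi, h, bump: BumpModel, nm_px: float):
    """Accumulate anisotropic-Gaussian bumps into ``img`` (heights combine by max)."""
    n_pix = img.shape[0]
    for xi, yi, ti, pi, hi in zip(x, y, theta, phi, h):
        s_minor = bump.gaussian_sigma_nm
        s_major = bump.gaussian_sigma_nm * (1.0 + bump.aspect_gain * ti)
        half = int(np.ceil(4.0 * s_major / nm_px)) + 1
        cx, cy = xi / nm_px, yi / nm_px
        c0, r0 = int(round(cx)), int(round(cy))
        cols = np.arange(max(0, c0 - half), min(n_pix, c0 + half + 1))
        rows = np.arange(max(0, r0 - half), min(n_pix, r0 + half + 1))
        if cols.size == 0 or rows.size == 0:
            continue
        dx = cols[None, :] * nm_px - xi
        dy = rows[:, None] * nm_px - yi
        ang = np.deg2rad(pi)
        u = dx * np.cos(ang) + dy * np.sin(ang)   # along major axis
        v = -dx * np.sin(ang) + dy * np.cos(ang)  # along minor axis
        bump_img = hi * np.exp(-0.5 * ((u / s_major) ** 2 + (v / s_minor) ** 2))
        sub = img[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
        np.maximum(sub, bump_img, out=sub)


def _tip_structure(tip_radius_nm: float, nm_px: float) -> np.ndarray:
    """Spherical-tip structuring element for grayscale dilation (apex at 0)."""
    r_px = int(np.ceil(tip_radius_nm / nm_px))
    ax = np.arange(-r_px, r_px + 1) * nm_px
    d2 = ax[None, :] ** 2 + ax[:, None] ** 2
    with np.errstate(invalid="ignore"):
        s = np.sqrt(tip_radius_nm ** 2 - d2) - tip_radius_nm
    s[d2 > tip_radius_nm ** 2] = -np.inf
    return s


def _render_capsule_frame(img, x, y, theta, phi, h, bump: BumpModel, nm_px: float):
    """Tilted-capsule height field: union of spheres along the protruding axis."""
    n_pix = img.shape[0]
    r = bump.cnt_radius_nm
    for xi, yi, ti, pi, hi in zip(x, y, theta, phi, h):
        # axis from the bilayer plane up to the apex at (xi, yi, hi)
        tan_t = math.tan(math.radians(ti))
        ang = math.radians(pi)
        # union of spheres (radius r) with centers along the rod axis from the
        # bilayer plane up to hi - r; the top sphere's crown puts the apex at hi
        n_samp = 41
        zc = np.linspace(0.0, max(hi - r, 0.0), n_samp)
        ax_x = xi + (zc - (hi - r)) * tan_t * math.cos(ang)
        ax_y = yi + (zc - (hi - r)) * tan_t * math.sin(ang)
        half = int(np.ceil((abs(hi) * tan_t + 3.0 * r) / nm_px)) + 2
        c0, r0 = int(round(xi / nm_px)), int(round(yi / nm_px))
        cols = np.arange(max(0, c0 - half), min(n_pix, c0 + half + 1))
        rows = np.arange(max(0, r0 - half), min(n_pix, r0 + half + 1))
        if cols.size == 0 or rows.size == 0:
            continue
        px = cols[None, :, None] * nm_px
        py = rows[:, None, None] * nm_px
        d2 = (px - ax_x[None, None, :]) ** 2 + (py - ax_y[None, None, :]) ** 2
        with np.errstate(invalid="ignore"):
            cap = zc[None, None, :] + np.sqrt(np.maximum(r * r - d2, 0.0)) * (
                d2 <= r * r
            )
        cap[d2 > r * r] = 0.0
        surf = cap.max(axis=2)
        sub = img[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
        np.maximum(sub, np.clip(surf, 0.0, None).astype(img.dtype), out=sub)


def render_movie(truth: GroundTruth, config: SimConfig) -> ImageStack:
    """Render ground-truth kinematics into a calibrated height-map movie.

    Each particle appears as a bump of peak height ``L·cosθ − T_b − T_w``
    above the zero-reference bilayer plane, elongated along its azimuth.
    Additive Gaussian pixel noise of sd ``noise_sd_nm`` is drawn from the
    noise stream spawned from the master seed, so identical configs give
    bit-identical movies.
    """
    n_pix = config.n_pixels
    nm_px = config.nm_per_pixel
    if truth.n_frames != config.n_frames or truth.n_particles != config.n_particles:
        raise ValueError("truth does not match config dimensions")
    inside = (
        (truth.x_nm >= 0) & (truth.x_nm <= config.field_size_nm)
        & (truth.y_nm >= 0) & (truth.y_nm <= config.field_size_nm)
    )
    if not inside.all():
        p, f = np.argwhere(~inside)[0]
        raise ValueError(f"particle {p} outside field at frame {f}")

    noise_stream = np.random.SeedSequence(config.seed).spawn(config.n_particles + 1)[-1]
    noise_rng = np.random.default_rng(noise_stream)
    tip = (
        _tip_structure(config.bump.tip_radius_nm, nm_px)
        if config.bump.renderer == "cylinder_dilation"
        else None
    )
    gdrift = np.asarray(config.global_drift_nm_per_frame, dtype=float)

    frames = np.zeros((config.n_frames, n_pix, n_pix), dtype=np.float32)
    for f in range(config.n_frames):
        img = frames[f]
        shift = gdrift * f
        xs = truth.x_nm[:, f] + shift[0]
        ys = truth.y_nm[:, f] + shift[1]
        if config.bump.renderer == "gaussian":
            _render_gaussian_frame(
                img, xs, ys, truth.theta_deg[:, f], truth.phi_deg[:, f],
                truth.h_nm[:, f], config.bump, nm_px,
            )
        else:
            _render_capsule_frame(
                img, xs, ys, truth.theta_deg[:, f], truth.phi_deg[:, f],
                truth.h_nm[:, f], config.bump, nm_px,
            )
            img[:] = ndimage.grey_dilation(img, structure=tip, mode="nearest")
        if config.noise_sd_nm > 0:
            img += noise_rng.normal(0.0, config.noise_sd_nm, size=img.shape).astype(
                np.float32
            )
    return ImageStack(
        frames,
        nm_per_pixel=nm_px,
        frame_interval_s=config.frame_interval_s,
        meta={"generator": "hsafm_spt.simulate", "seed": config.seed},
    )


def simulate_movie(config: SimConfig) -> tuple[GroundTruth, ImageStack]:
    """Convenience: trajectories + rendered movie in one call."""
    truth = simulate_trajectories(config)
    return truth, render_movie(truth, config)


def write_fixture(truth: GroundTruth, stack: ImageStack, config: SimConfig,
                  out_dir: str | Path) -> dict:
    """Persist a movie bundle: TIFF + calibration sidecar + truth CSV + config JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "movie": out / "movie.tif",
        "truth": out / "truth.csv",
        "config": out / "config.json",
    }
    write_stack(stack, paths["movie"])
    truth.to_frame().to_csv(paths["truth"], index=False)
    paths["config"].write_text(json.dumps(config.to_dict(), indent=2))
    return {k: str(v) for k, v in paths.items()}


def read_fixture(out_dir: str | Path) -> tuple[GroundTruth, ImageStack, SimConfig]:
    """Load a bundle written by :func:`write_fixture` (lossless round trip)."""
    out = Path(out_dir)
    stack = read_stack(out / "movie.tif")
    config = SimConfig.from_dict(json.loads((out / "config.json").read_text()))
    truth = GroundTruth.from_frame(pd.read_csv(out / "truth.csv"),
                                   frame_interval_s=config.frame_interval_s)
    return truth, stack, config
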
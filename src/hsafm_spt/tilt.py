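"""Tilt-angle geometry and rotational-step analysis.

A rigid rod of length L spanning a supported bilayer (thickness T_b) and
its hydration water layer (T_w) protrudes by an apparent height
``h = L·cosθ − T_b − T_w`` when tilted by θ from the membrane normal.  The
rod length is calibrated from the maximum observed height (maximum height =
zero tilt), and per-frame heights invert to tilt angles via
``θ = arccos((h + T_b + T_w) / L)``.

In-plane rotation is read from the elongation direction of the imaged bump
(second-moment principal axis).  Because a rod's image has two-fold
symmetry the azimuth φ is defined modulo 180° and only step statistics —
not cumulative rotation — are computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "TiltModelParams",
    "TiltTrace",
    "OrientationTrace",
    "RotationStepHistogram",
    "NonPhysicalHeightError",
    "WindowClippedError",
    "estimate_length",
    "tilt_from_height",
    "height_from_tilt",
    "tilt_trace",
    "tilt_histogram",
    "orientation_from_bump",
    "orientation_trace",
    "wrap_step_deg",
    "rotation_steps",
]


class NonPhysicalHeightError(ValueError):
    """Apparent height below the bilayer by more than T_b + T_w."""


class WindowClippedError(ValueError):
    """Requested analysis window extends past the frame edge."""


@dataclass
class TiltModelParams:
    """Rigid-rod geometry: bilayer thickness, water layer, rod length (nm)."""

    L: float
    T_b: float = 4.1
    T_w: float = 1.0

    def __post_init__(self) -> None:
        if not self.T_b + self.T_w > 0:
            raise ValueError("T_b + T_w must be positive")
        if not self.L > self.T_b + self.T_w:
            raise ValueError("rod length L must exceed T_b + T_w")

    @property
    def max_height_nm(self) -> float:
        """Apparent height of an upright rod."""
        return self.L - self.T_b - self.T_w


@dataclass
class TiltTrace:
    time_s: np.ndarray
    theta_deg: np.ndarray
    clamped: np.ndarray          # True where h overshot the upright height
    particle_id: int = 0


@dataclass
class OrientationTrace:
    """Per-frame bump azimuth (deg, [0, 180)) and shape-asymmetry ratio.

    φ is NaN ("undefined") wherever the asymmetry ratio falls below the
    threshold used to build the trace — a near-circular bump carries no
    orientation information.
    """

    time_s: np.ndarray
    phi_deg: np.ndarray
    asymmetry_ratio: np.ndarray
    particle_id: int = 0
    frames: np.ndarray | None = None


@dataclass
class RotationStepHistogram:
    step_deg: np.ndarray         # wrapped to (−90, 90]
    bin_edges: np.ndarray
    counts: np.ndarray
    gaussian_mu_deg: float
    gaussian_sigma_deg: float
    mle_mu_deg: float            # sample mean/sd of the raw wrapped steps
    mle_sigma_deg: float

    @property
    def n_steps(self) -> int:
        return int(self.step_deg.size)


def estimate_length(h_series, T_b: float = 4.1, T_w: float = 1.0,
                    quantile: float | None = None) -> TiltModelParams:
    """Calibrate the rod length from an apparent-height series.

    The maximum observed height corresponds to zero tilt, so
    ``L = max(h) + T_b + T_w``.  On noisy series a high ``quantile`` (e.g.
    0.99) may replace the maximum to reject single-pixel outliers.
    """
    h = np.asarray(h_series, dtype=float)
    h = h[np.isfinite(h)]
    if h.size == 0:
        raise ValueError("height series is empty")
    h_max = float(np.max(h) if quantile is None else np.quantile(h, quantile))
    if h_max <= 0:
        raise NonPhysicalHeightError(
            f"maximum apparent height {h_max:.3g} nm is not positive"
        )
    return TiltModelParams(L=h_max + T_b + T_w, T_b=T_b, T_w=T_w)


def height_from_tilt(theta_deg, params: TiltModelParams) -> np.ndarray:
    """Forward model h(θ) = L·cosθ − T_b − T_w."""
    return params.L * np.cos(np.deg2rad(np.asarray(theta_deg, float))) \
        - params.T_b - params.T_w


def tilt_from_height(h, params: TiltModelParams, return_clamped: bool = False):
    """Invert apparent height to tilt angle: θ = arccos((h + T_b + T_w)/L).

    Heights slightly above the upright value (measurement noise) clamp to
    θ = 0; the clamp mask is returned when ``return_clamped=True``.  Heights
    below the bilayer by more than T_b + T_w have no geometric solution and
    raise :class:`NonPhysicalHeightError`.
    """
    h_arr = np.asarray(h, dtype=float)
    if not np.all(np.isfinite(h_arr)):
        raise ValueError("heights must be finite")
    ratio = (h_arr + params.T_b + params.T_w) / params.L
    if np.any(ratio <= 0):
        bad = h_arr[ratio <= 0]
        raise NonPhysicalHeightError(
            f"apparent height {bad.ravel()[0]:.3g} nm is below the bilayer "
            f"by more than T_b + T_w = {params.T_b + params.T_w:.3g} nm"
        )
    clamped = ratio > 1.0
    theta = np.degrees(np.arccos(np.clip(ratio, -1.0, 1.0)))
    theta = np.where(clamped, 0.0, theta)
    if np.isscalar(h) or np.ndim(h) == 0:
        theta = float(theta)
        clamped = bool(clamped)
    if return_clamped:
        return theta, clamped
    return theta


def tilt_trace(track, params: TiltModelParams,
               frame_interval_s: float) -> TiltTrace:
    """Per-frame tilt angles for one trajectory's apparent heights."""
    heights = track.heights_nm if hasattr(track, "heights_nm") else np.asarray(track)
    if heights.size == 0 or not np.any(np.isfinite(heights)):
        raise ValueError("track carries no peak-height information")
    frames = track.frames if hasattr(track, "frames") else np.arange(heights.size)
    theta, clamped = tilt_from_height(heights, params, return_clamped=True)
    pid = getattr(track, "particle_id", 0)
    return TiltTrace(
        time_s=frames * frame_interval_s,
        theta_deg=np.asarray(theta, dtype=float),
        clamped=np.asarray(clamped, dtype=bool),
        particle_id=pid,
    )


def tilt_histogram(trace: TiltTrace, bin_width_deg: float = 2.5):
    """Angle/count table of the tilt distribution (polar-plot ready).

    Returns ``(bin_edges_deg, counts)`` with bins spanning [0°, 90°).
    """
    edges = np.arange(0.0, 90.0 + bin_width_deg, bin_width_deg)
    counts, edges = np.histogram(trace.theta_deg, bins=edges)
    return edges, counts


def orientation_from_bump(frame: np.ndarray, x_px: float, y_px: float,
                          window_px: int = 7, nm_per_pixel: float = 1.0,
                          min_asymmetry: float = 1.15):
    """Bump azimuth from the second-moment tensor of its neighbourhood.

    The window (half-width ``window_px``) around the detection is
    background-subtracted (median of the window border) and its
    height-weighted second moments diagonalised.  φ is the principal-axis
    direction in image coordinates mapped to [0, 180); the asymmetry ratio
    is √(λ_major/λ_minor).  A ratio below ``min_asymmetry`` means the bump
    is too round to orient: φ is returned as NaN.
    """
    frame = np.asarray(frame, dtype=float)
    r0, c0 = int(round(y_px)), int(round(x_px))
    h = int(window_px)
    if (r0 - h < 0 or c0 - h < 0 or r0 + h >= frame.shape[0]
            or c0 + h >= frame.shape[1]):
        raise WindowClippedError(
            f"window of half-width {h} around ({x_px:.1f}, {y_px:.1f}) px "
            "extends past the frame edge"
        )
    win = frame[r0 - h:r0 + h + 1, c0 - h:c0 + h + 1].copy()
    border = np.concatenate([win[0], win[-1], win[1:-1, 0], win[1:-1, -1]])
    w = np.clip(win - np.median(border), 0.0, None)
    tot = w.sum()
    if tot <= 0:
        return np.nan, 1.0
    yy, xx = np.mgrid[0:win.shape[0], 0:win.shape[1]]
    cx = (w * xx).sum() / tot
    cy = (w * yy).sum() / tot
    mxx = (w * (xx - cx) ** 2).sum() / tot
    myy = (w * (yy - cy) ** 2).sum() / tot
    mxy = (w * (xx - cx) * (yy - cy)).sum() / tot
    cov = np.array([[mxx, mxy], [mxy, myy]]) * nm_per_pixel ** 2
    evals, evecs = np.linalg.eigh(cov)      # ascending
    lam_minor, lam_major = float(evals[0]), float(evals[1])
    if lam_minor <= 0:
        lam_minor = np.finfo(float).tiny
    ratio = float(np.sqrt(lam_major / lam_minor))
    major = evecs[:, 1]                     # (x, y) components
    phi = float(np.degrees(np.arctan2(major[1], major[0])) % 180.0)
    if ratio < min_asymmetry:
        return np.nan, ratio
    return phi, ratio


def orientation_trace(stack, track, window_px: int = 7,
                      min_asymmetry: float = 1.15) -> OrientationTrace:
    """Azimuth and asymmetry per frame of a trajectory over its movie."""
    phis, ratios, frames = [], [], []
    for det in track.detections:
        x_px = det.x_nm / stack.nm_per_pixel
        y_px = det.y_nm / stack.nm_per_pixel
        try:
            phi, ratio = orientation_from_bump(
                stack.data[det.frame], x_px, y_px, window_px=window_px,
                nm_per_pixel=stack.nm_per_pixel, min_asymmetry=min_asymmetry,
            )
        except WindowClippedError:
            phi, ratio = np.nan, np.nan
        phis.append(phi)
        ratios.append(ratio)
        frames.append(det.frame)
    frames = np.asarray(frames)
    return OrientationTrace(
        time_s=frames * stack.frame_interval_s,
        phi_deg=np.asarray(phis, dtype=float),
        asymmetry_ratio=np.asarray(ratios, dtype=float),
        particle_id=track.particle_id,
        frames=frames,
    )


def wrap_step_deg(d) -> np.ndarray:
    """Wrap orientation steps into (−90°, 90°] (180°-periodic shape symmetry)."""
    return 90.0 - np.mod(90.0 - np.asarray(d, dtype=float), 180.0)


def _gauss(x, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def rotation_steps(trace, bin_width_deg: float = 10.0,
                   allow_gaps: bool = False) -> RotationStepHistogram:
    """Step-angle statistics of an orientation trace.

    Steps Δφ between consecutive defined orientations are wrapped to
    (−90°, 90°]; frames with undefined φ break the chain (no step is taken
    across them unless ``allow_gaps=True``).  The headline (μ, σ) come from
    a least-squares Gaussian fit to the binned counts; the sample mean/sd of
    the raw wrapped steps is reported alongside.
    """
    if isinstance(trace, OrientationTrace):
        phi = np.asarray(trace.phi_deg, dtype=float)
        frames = (np.asarray(trace.frames) if trace.frames is not None
                  else np.arange(phi.size))
    else:
        phi = np.asarray(trace, dtype=float)
        frames = np.arange(phi.size)
    defined = np.isfinite(phi)
    if defined.sum() < 3:
        raise ValueError("need at least 3 defined orientations")
    idx = np.flatnonzero(defined)
    consecutive = np.diff(frames[idx]) == 1
    pairs = idx[:-1][consecutive | allow_gaps], idx[1:][consecutive | allow_gaps]
    steps = wrap_step_deg(phi[pairs[1]] - phi[pairs[0]])
    if steps.size < 2:
        raise ValueError("too few consecutive orientation pairs to form steps")

    edges = np.arange(-90.0, 90.0 + bin_width_deg, bin_width_deg)
    counts, edges = np.histogram(steps, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mle_mu = float(steps.mean())
    mle_sigma = float(steps.std(ddof=0))
    if mle_sigma == 0.0:
        mu_fit, sigma_fit = mle_mu, 0.0
    else:
        try:
            popt, _ = optimize.curve_fit(
                _gauss, centers, counts,
                p0=[counts.max(), mle_mu, max(mle_sigma, bin_width_deg / 2)],
                maxfev=2000,
            )
            mu_fit, sigma_fit = float(popt[1]), float(abs(popt[2]))
        except RuntimeError:
            mu_fit, sigma_fit = mle_mu, mle_sigma
    return RotationStepHistogram(
        step_deg=steps,
        bin_edges=edges,
        counts=counts,
        gaussian_mu_deg=mu_fit,
        gaussian_sigma_deg=sigma_fit,
        mle_mu_deg=mle_mu,
        mle_sigma_deg=mle_sigma,
    )
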
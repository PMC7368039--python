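"""Trajectory extraction from HS-AFM height movies.

Three stages, mirroring the usual ImageJ/TrackMate workflow for these data:
phase-correlation drift correction, Laplacian-of-Gaussian spot detection
with subpixel refinement, and greedy nearest-neighbour frame-to-frame
linking with gap closing.  A TrackMate-style CSV dialect is read and
written so externally curated tracks can enter the analysis unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats
from skimage.feature import blob_log
from skimage.registration import phase_cross_correlation

from .io import ImageStack

__all__ = [
    "Detection",
    "Trajectory",
    "LinkingParams",
    "correct_drift",
    "detect_spots",
    "detect_movie",
    "link_detections",
    "read_tracks_csv",
    "write_tracks_csv",
    "track_movie",
]

# default gate: 3 sigma of a Brownian step at the top of the observed D range
# (D_max = 1e-3 um^2/s, dt = 0.5 s): 3 * sqrt(4 * 1e3 nm^2/s * 0.5 s) ~ 134 nm
D_MAX_DEFAULT_UM2_S = 1.0e-3


def default_max_step_nm(frame_interval_s: float,
                        d_max_um2_s: float = D_MAX_DEFAULT_UM2_S) -> float:
    return 3.0 * np.sqrt(4.0 * d_max_um2_s * 1.0e6 * frame_interval_s)


@dataclass
class Detection:
    """A single spot in one frame, in physical units."""

    frame: int
    x_nm: float
    y_nm: float
    peak_height_nm: float
    quality: float = 0.0
    #: background-subtracted, height-weighted second-moment tensor
    #: (m_xx, m_yy, m_xy) of the bump neighbourhood, in nm^2
    moments: tuple = (np.nan, np.nan, np.nan)


@dataclass
class Trajectory:
    """Time-ordered detections for one particle."""

    particle_id: int
    detections: list
    gaps: list = field(default_factory=list)

    def __post_init__(self) -> None:
        frames = self.frames
        if np.any(np.diff(frames) <= 0):
            raise ValueError("detections must have strictly increasing frames")

    def __len__(self) -> int:
        return len(self.detections)

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame for d in self.detections], dtype=int)

    @property
    def positions_nm(self) -> np.ndarray:
        return np.array([[d.x_nm, d.y_nm] for d in self.detections], dtype=float)

    @property
    def heights_nm(self) -> np.ndarray:
        return np.array([d.peak_height_nm for d in self.detections], dtype=float)


@dataclass
class LinkingParams:
    max_step_nm: float = default_max_step_nm(0.5)
    max_gap_frames: int = 2
    min_track_length: int = 10

    def __post_init__(self) -> None:
        if self.max_step_nm <= 0 or self.max_gap_frames < 0:
            raise ValueError("max_step_nm > 0 and max_gap_frames >= 0 required")
        if self.min_track_length < 4:
            raise ValueError("min_track_length must be >= 4")


def correct_drift(stack: ImageStack, upsample_factor: int = 50,
                  drift_model: str = "linear"
                  ) -> tuple[ImageStack, np.ndarray]:
    """Remove frame-to-frame mechanical drift by phase cross-correlation.

    With ``drift_model='cumulative'`` the translation between consecutive
    frames is estimated with subpixel precision, summed, and applied as-is.
    With ``'linear'`` (default) each frame is registered directly against
    the first frame and a constant drift velocity is extracted by a
    per-axis Theil–Sen fit of shift versus frame index: mechanical drift is
    smooth on the movie timescale, the long-baseline registration avoids
    the error accumulation of chained consecutive estimates, and the robust
    slope keeps mobile particles — whose displacements contaminate
    individual estimates — from being mistaken for stage motion.  Returns
    the corrected stack and the applied per-frame shifts in pixels, as
    ``(n_frames, 2)`` in ``(row, col)`` order.
    """
    if stack.n_frames < 2:
        raise ValueError("drift correction needs at least 2 frames")
    if drift_model not in ("cumulative", "linear"):
        raise ValueError(f"unknown drift_model {drift_model!r}")
    data = stack.data

    def _register(a, b, f):
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            warnings.warn(
                f"constant frame near index {f}; assuming zero drift",
                RuntimeWarning,
                stacklevel=3,
            )
            return np.zeros(2)
        est, _, _ = phase_cross_correlation(
            a, b, upsample_factor=upsample_factor, normalization=None
        )
        return est

    if drift_model == "linear":
        raw = np.zeros((stack.n_frames, 2))
        for f in range(1, stack.n_frames):
            raw[f] = _register(data[0], data[f], f)
        frames = np.arange(stack.n_frames)
        if stack.n_frames == 2:
            velocity = raw[1]
        else:
            velocity = np.array([
                stats.theilslopes(raw[:, ax], frames).slope for ax in (0, 1)
            ])
        shifts = frames[:, None] * velocity[None, :]
    else:
        steps = np.array([
            _register(data[f - 1], data[f], f) for f in range(1, stack.n_frames)
        ])
        shifts = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
    corrected = np.empty_like(data)
    corrected[0] = data[0]
    for f in range(1, stack.n_frames):
        if np.allclose(shifts[f], 0.0):
            corrected[f] = data[f]
        else:
            corrected[f] = ndimage.shift(
                data[f], shifts[f], order=1, mode="nearest"
            )
    out = ImageStack(corrected, stack.nm_per_pixel, stack.frame_interval_s,
                     meta={**stack.meta, "drift_corrected": True})
    return out, shifts


def _gaussian2d(params, xx, yy):
    amp, x0, y0, a, b, c, off = params
    return amp * np.exp(-(a * (xx - x0) ** 2 + 2 * b * (xx - x0) * (yy - y0)
                          + c * (yy - y0) ** 2)) + off


def _refine_gaussian(window: np.ndarray, x0: float, y0: float, sigma_px: float):
    """Fit an elliptical 2-D Gaussian to a detection window.

    Returns (amplitude, x, y) in window pixel coordinates, or None if the
    fit fails or wanders out of the window.
    """
    h, w = window.shape
    yy, xx = np.mgrid[0:h, 0:w]
    amp0 = float(window.max()) - float(np.median(window))
    q0 = 1.0 / (2.0 * sigma_px ** 2)
    p0 = [amp0, x0, y0, q0, 0.0, q0, float(np.median(window))]

    def resid(p):
        return (_gaussian2d(p, xx, yy) - window).ravel()

    try:
        res = optimize.least_squares(resid, p0, method="lm", max_nfev=200)
    except Exception:
        return None
    amp, xf, yf, a, b, c, off = res.x
    if not (0 <= xf < w and 0 <= yf < h) or amp <= 0:
        return None
    if a <= 0 or c <= 0 or a * c - b * b <= 0:  # not an elliptical peak
        return None
    return amp, xf, yf


def _window_moments(window: np.ndarray, nm_per_pixel: float):
    """Height-weighted centroid and second moments of a background-subtracted
    window; negative pixels are clipped to zero weight."""
    w = np.clip(window, 0.0, None)
    tot = w.sum()
    if tot <= 0:
        return None
    yy, xx = np.mgrid[0:window.shape[0], 0:window.shape[1]]
    cx = (w * xx).sum() / tot
    cy = (w * yy).sum() / tot
    mxx = (w * (xx - cx) ** 2).sum() / tot * nm_per_pixel ** 2
    myy = (w * (yy - cy) ** 2).sum() / tot * nm_per_pixel ** 2
    mxy = (w * (xx - cx) * (yy - cy)).sum() / tot * nm_per_pixel ** 2
    return cx, cy, (mxx, myy, mxy)


def detect_spots(
    frame: np.ndarray,
    nm_per_pixel: float,
    frame_index: int = 0,
    min_height_nm: float = 1.5,
    sigma_range_nm: tuple = (2.0, 6.0),
    refine: str = "gaussian",
) -> list:
    """Detect bump-like spots in one calibrated height frame.

    Laplacian-of-Gaussian blob detection over ``sigma_range_nm`` proposes
    candidates on the median-background-subtracted frame; candidates whose
    local peak rises less than ``min_height_nm`` above background are
    dropped.  Positions are refined to subpixel precision by an elliptical
    Gaussian fit (``refine='gaussian'``, also refining the peak height) or a
    height-weighted centroid (``refine='centroid'``).  Each detection
    carries the second-moment tensor of its neighbourhood for downstream
    orientation analysis.
    """
    frame = np.asarray(frame, dtype=float)
    background = float(np.median(frame))
    bs = frame - background
    lo = max(1.0, sigma_range_nm[0] / nm_per_pixel)
    hi = max(lo + 0.5, sigma_range_nm[1] / nm_per_pixel)
    blobs = blob_log(
        np.clip(bs, 0.0, None),
        min_sigma=lo,
        max_sigma=hi,
        num_sigma=5,
        threshold=0.15 * min_height_nm,
    )
    detections: list[Detection] = []
    n_pix_r, n_pix_c = frame.shape
    for row, col, sigma in blobs:
        r0, c0 = int(round(row)), int(round(col))
        # peak height above background, from the 3x3 neighbourhood maximum
        rlo, rhi = max(0, r0 - 1), min(n_pix_r, r0 + 2)
        clo, chi = max(0, c0 - 1), min(n_pix_c, c0 + 2)
        peak = float(bs[rlo:rhi, clo:chi].max())
        if peak < min_height_nm:
            continue
        half = max(3, int(np.ceil(2.5 * sigma)))
        wr = slice(max(0, r0 - half), min(n_pix_r, r0 + half + 1))
        wc = slice(max(0, c0 - half), min(n_pix_c, c0 + half + 1))
        window = bs[wr, wc]
        mom = _window_moments(window, nm_per_pixel)
        if mom is None:
            continue
        cx, cy, moments = mom
        x_px, y_px = wc.start + cx, wr.start + cy
        if refine == "gaussian":
            fit = _refine_gaussian(window, cx, cy, sigma)
            if fit is not None:
                amp, xf, yf = fit
                peak = float(amp)
                x_px, y_px = wc.start + xf, wr.start + yf
        detections.append(
            Detection(
                frame=frame_index,
                x_nm=float(x_px * nm_per_pixel),
                y_nm=float(y_px * nm_per_pixel),
                peak_height_nm=peak,
                quality=peak,
                moments=moments,
            )
        )
    return detections


def detect_movie(stack: ImageStack, **kwargs) -> list:
    """Run :func:`detect_spots` on every frame; returns a flat, frame-sorted list."""
    detections: list[Detection] = []
    for f in range(stack.n_frames):
        detections.extend(
            detect_spots(stack.data[f], stack.nm_per_pixel, frame_index=f, **kwargs)
        )
    return detections


def link_detections(detections: list, params: LinkingParams) -> list:
    """Link detections into trajectories by greedy nearest-neighbour assignment.

    Frame pairs are processed in order; candidate (track-end, detection)
    pairs within the gate are assigned smallest-distance-first (ties broken
    by lowest track id).  A track missing a detection may be continued
    across up to ``max_gap_frames`` skipped frames, with the gate radius
    scaled by ``sqrt(gap + 1)`` to account for the longer diffusion time.
    Tracks shorter than ``min_track_length`` detections are discarded.
    """
    if not detections:
        return []
    by_frame: dict[int, list[Detection]] = {}
    for d in detections:
        by_frame.setdefault(int(d.frame), []).append(d)

    active: list[dict] = []   # {"id", "dets": [Detection], "gaps": [int]}
    finished: list[dict] = []
    next_id = 0
    frames = sorted(by_frame)
    for f in range(frames[0], frames[-1] + 1):
        dets = by_frame.get(f, [])
        # candidate pairs: active track ends vs this frame's detections
        pairs = []
        for ti, tr in enumerate(active):
            last = tr["dets"][-1]
            gap = f - last.frame - 1
            gate = params.max_step_nm * np.sqrt(gap + 1.0)
            for di, d in enumerate(dets):
                dist = np.hypot(d.x_nm - last.x_nm, d.y_nm - last.y_nm)
                if dist <= gate:
                    pairs.append((dist, tr["id"], ti, di))
        pairs.sort(key=lambda p: (p[0], p[1]))
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for dist, _tid, ti, di in pairs:
            if ti in used_tracks or di in used_dets:
                continue
            tr = active[ti]
            gap_frames = list(range(tr["dets"][-1].frame + 1, f))
            tr["gaps"].extend(gap_frames)
            tr["dets"].append(dets[di])
            used_tracks.add(ti)
            used_dets.add(di)
        # unmatched detections seed new tracks
        for di, d in enumerate(dets):
            if di not in used_dets:
                active.append({"id": next_id, "dets": [d], "gaps": []})
                next_id += 1
        # retire tracks that exceeded the gap allowance
        still = []
        for tr in active:
            if f - tr["dets"][-1].frame > params.max_gap_frames:
                finished.append(tr)
            else:
                still.append(tr)
        active = still
    finished.extend(active)

    tracks = [
        Trajectory(particle_id=i, detections=tr["dets"], gaps=tr["gaps"])
        for i, tr in enumerate(
            sorted(
                (t for t in finished if len(t["dets"]) >= params.min_track_length),
                key=lambda t: t["id"],
            )
        )
    ]
    return tracks


MANDATORY_COLUMNS = ["TRACK_ID", "FRAME", "POSITION_X", "POSITION_Y"]
EXTENSION_COLUMNS = ["PEAK_HEIGHT", "QUALITY", "M_XX", "M_YY", "M_XY"]


def write_tracks_csv(tracks: list, path: str | Path) -> None:
    """Write trajectories in the TrackMate-style dialect (positions in nm)."""
    rows = []
    for tr in tracks:
        for d in tr.detections:
            rows.append(
                {
                    "TRACK_ID": tr.particle_id,
                    "FRAME": d.frame,
                    "POSITION_X": d.x_nm,
                    "POSITION_Y": d.y_nm,
                    "PEAK_HEIGHT": d.peak_height_nm,
                    "QUALITY": d.quality,
                    "M_XX": d.moments[0],
                    "M_YY": d.moments[1],
                    "M_XY": d.moments[2],
                }
            )
    pd.DataFrame(rows, columns=MANDATORY_COLUMNS + EXTENSION_COLUMNS).to_csv(
        path, index=False
    )


def read_tracks_csv(path: str | Path) -> list:
    """Read the TrackMate-style dialect back into trajectories.

    Files carrying only the four mandatory columns load fine; height and
    moment fields are then NaN ("missing").  Rows may appear in any order.
    """
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tracks CSV is missing mandatory column(s): {missing}")
    for c in EXTENSION_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    df = df.sort_values(["TRACK_ID", "FRAME"])
    tracks = []
    for tid, grp in df.groupby("TRACK_ID", sort=True):
        dets = [
            Detection(
                frame=int(r.FRAME),
                x_nm=float(r.POSITION_X),
                y_nm=float(r.POSITION_Y),
                peak_height_nm=float(r.PEAK_HEIGHT),
                quality=float(r.QUALITY) if np.isfinite(r.QUALITY) else 0.0,
                moments=(float(r.M_XX), float(r.M_YY), float(r.M_XY)),
            )
            for r in grp.itertuples()
        ]
        frames = [d.frame for d in dets]
        gaps = sorted(set(range(frames[0], frames[-1] + 1)) - set(frames))
        tracks.append(Trajectory(particle_id=int(tid), detections=dets, gaps=gaps))
    return tracks


def track_movie(
    stack: ImageStack,
    linking: LinkingParams | None = None,
    drift_correct: bool = True,
    **detect_kwargs,
) -> tuple[list, np.ndarray]:
    """Full tracking stage: optional drift correction, detection, linking.

    Returns the trajectories and the applied per-frame drift shifts in
    pixels (zeros when ``drift_correct=False``).
    """
    shifts = np.zeros((stack.n_frames, 2))
    if drift_correct:
        stack, shifts = correct_drift(stack)
    if linking is None:
        linking = LinkingParams(
            max_step_nm=default_max_step_nm(stack.frame_interval_s)
        )
    detections = detect_movie(stack, **detect_kwargs)
    return link_detections(detections, linking), shifts
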
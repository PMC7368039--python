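"""MSD-based diffusion analysis for single-particle trajectories.

Time-averaged mean-square-displacement curves with overlapping pairs,
Brownian (``MSD = 4·D·t + b``) and directed (``MSD = 4·D·t + (v·t)² + b``)
model fits restricted to the first third of the available lags, log-normal
ensemble statistics of per-particle diffusion coefficients, and helpers for
periodic-boundary centre-of-mass series.  D is reported in µm²/s throughout;
internal arithmetic is in nm and s (1 µm² = 1e6 nm²).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "MSDCurve",
    "DiffusionEstimate",
    "EnsembleStats",
    "TrackTooShortError",
    "compute_msd",
    "fit_brownian",
    "fit_directed",
    "fit_lognormal",
    "composition_trend",
    "unwrap_periodic",
    "wrap_periodic",
]

NM2_PER_UM2 = 1.0e6


class TrackTooShortError(ValueError):
    """Trajectory or MSD curve has too few points for the requested fit."""


@dataclass
class MSDCurve:
    """Time-averaged MSD: lag times (s), MSD (nm²), and pair counts per lag."""

    lag_s: np.ndarray
    msd_nm2: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        self.lag_s = np.asarray(self.lag_s, dtype=float)
        self.msd_nm2 = np.asarray(self.msd_nm2, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if np.any(np.diff(self.lag_s) <= 0):
            raise ValueError("lag times must be strictly increasing")
        if np.any(self.msd_nm2 < 0):
            raise ValueError("MSD values must be non-negative")

    @property
    def n_lags(self) -> int:
        return self.lag_s.size


@dataclass
class DiffusionEstimate:
    """Fitted diffusion parameters for one trajectory."""

    D_um2_s: float
    model: str                       # "brownian" | "directed"
    intercept_nm2: float
    fit_lags: np.ndarray             # indices of the lags used in the fit
    r2: float
    rss_nm4: float
    v_nm_s: float | None = None      # drift speed, directed model only
    clamped_D: bool = False          # D constraint was active
    clamped_v: bool = False          # v^2 constraint was active (directed)


@dataclass
class EnsembleStats:
    """Log-normal summary of per-particle D values for one bilayer composition."""

    composition_label: str
    D_um2_s: np.ndarray
    mu_log: float
    sigma_log: float
    arithmetic_mean_D: float
    geometric_mean_D: float
    n_excluded: int = 0
    dmpc_fraction: float | None = None

    @property
    def n(self) -> int:
        return int(np.asarray(self.D_um2_s).size)


def _track_arrays(track, frame_interval_s):
    """Accept a tracking.Trajectory or a plain (n, 2) position array."""
    if hasattr(track, "positions_nm"):
        frames = track.frames
        pos = track.positions_nm
        if frame_interval_s is None:
            raise ValueError("frame_interval_s is required with a Trajectory")
    else:
        pos = np.asarray(track, dtype=float)
        frames = np.arange(pos.shape[0])
        if frame_interval_s is None:
            frame_interval_s = 1.0
    return frames, pos, frame_interval_s


def compute_msd(track, frame_interval_s: float | None = None,
                min_track_length: int = 4) -> MSDCurve:
    """Time-averaged MSD with overlapping pairs.

    ``MSD(kΔt)`` is the mean of ``|r(i+k) − r(i)|²`` over every index pair
    ``(i, i+k)`` for which both frames were observed; pairs spanning a
    detection gap are excluded, and the number of pairs entering each lag is
    reported.  ``track`` may be a :class:`~hsafm_spt.tracking.Trajectory`
    (gaps honoured via its frame indices) or an ``(n, 2)`` array of
    positions in nm at uniform ``frame_interval_s``.
    """
    frames, pos, dt = _track_arrays(track, frame_interval_s)
    if len(frames) < min_track_length:
        raise TrackTooShortError(
            f"track has {len(frames)} points; need >= {min_track_length}"
        )
    # dense frame-indexed array with NaN at gaps
    span = frames[-1] - frames[0] + 1
    dense = np.full((span, 2), np.nan)
    dense[frames - frames[0]] = pos
    lags = np.arange(1, span)
    msd = np.empty(lags.size)
    n_pairs = np.empty(lags.size, dtype=int)
    for j, k in enumerate(lags):
        disp = dense[k:] - dense[:-k]
        sq = np.einsum("ij,ij->i", disp, disp)
        valid = np.isfinite(sq)
        n_pairs[j] = int(valid.sum())
        msd[j] = sq[valid].mean() if n_pairs[j] else np.nan
    keep = n_pairs > 0
    return MSDCurve(lag_s=lags[keep] * dt, msd_nm2=msd[keep], n_pairs=n_pairs[keep])


def _fit_window(curve: MSDCurve, min_lags: int = 6) -> np.ndarray:
    """First-third rule: fit the first ⌊N/3⌋ lags (at least 2)."""
    if curve.n_lags < min_lags:
        raise TrackTooShortError(
            f"MSD curve has {curve.n_lags} lags; need >= {min_lags} "
            "so the first-1/3 window holds >= 2 points"
        )
    return np.arange(curve.n_lags // 3)


def _bounded_lsq(A: np.ndarray, y: np.ndarray, lower: np.ndarray):
    """Least squares with per-coefficient lower bounds; returns (x, active)."""
    res = optimize.lsq_linear(A, y, bounds=(lower, np.full(lower.shape, np.inf)))
    active = res.active_mask != 0
    x = res.x.copy()
    x[active] = lower[active]  # snap to the bound exactly (solver leaves ~1e-20)
    return x, active


def _goodness(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float]:
    rss = float(np.sum((y - yhat) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return r2, rss


def fit_brownian(curve: MSDCurve, fit_intercept: bool = True,
                 weights: str | None = None) -> DiffusionEstimate:
    """Fit ``MSD = 4·D·lag + intercept`` over the first third of the lags.

    Least squares with the physical constraint D ≥ 0 (a negative
    unconstrained slope clamps to D = 0 and sets ``clamped_D``).  The free
    intercept absorbs localisation noise; ``fit_intercept=False`` forces it
    through the origin.  ``weights='n_pairs'`` weights each lag by the
    number of displacement pairs averaged into it.
    """
    idx = _fit_window(curve)
    lag = curve.lag_s[idx]
    y = curve.msd_nm2[idx]
    cols = [4.0 * lag]
    lower = [0.0]
    if fit_intercept:
        cols.append(np.ones_like(lag))
        lower.append(-np.inf)
    A = np.column_stack(cols)
    w = np.sqrt(curve.n_pairs[idx].astype(float)) if weights == "n_pairs" else None
    if w is not None:
        x, active = _bounded_lsq(A * w[:, None], y * w, np.array(lower))
    else:
        x, active = _bounded_lsq(A, y, np.array(lower))
    D_nm2_s = x[0]
    intercept = x[1] if fit_intercept else 0.0
    r2, rss = _goodness(y, A @ x)
    return DiffusionEstimate(
        D_um2_s=D_nm2_s / NM2_PER_UM2,
        model="brownian",
        intercept_nm2=float(intercept),
        fit_lags=idx,
        r2=r2,
        rss_nm4=rss,
        clamped_D=bool(active[0]),
    )


def fit_directed(curve: MSDCurve, fit_intercept: bool = True,
                 weights: str | None = None) -> DiffusionEstimate:
    """Fit the directed-diffusion model ``MSD = 4·D·lag + (v·lag)² + intercept``.

    Both physical coefficients are constrained (D ≥ 0, v² ≥ 0); a negative
    unconstrained quadratic term collapses to v = 0 (flagged), recovering
    the Brownian fit.  Because the Brownian model is nested inside this one
    under the same constraints, the directed fit's residual sum of squares
    never exceeds the Brownian fit's on the same window.
    """
    idx = _fit_window(curve)
    lag = curve.lag_s[idx]
    y = curve.msd_nm2[idx]
    cols = [4.0 * lag, lag ** 2]
    lower = [0.0, 0.0]
    if fit_intercept:
        cols.append(np.ones_like(lag))
        lower.append(-np.inf)
    A = np.column_stack(cols)
    w = np.sqrt(curve.n_pairs[idx].astype(float)) if weights == "n_pairs" else None
    if w is not None:
        x, active = _bounded_lsq(A * w[:, None], y * w, np.array(lower))
    else:
        x, active = _bounded_lsq(A, y, np.array(lower))
    D_nm2_s, v2 = x[0], x[1]
    intercept = x[2] if fit_intercept else 0.0
    r2, rss = _goodness(y, A @ x)
    return DiffusionEstimate(
        D_um2_s=D_nm2_s / NM2_PER_UM2,
        model="directed",
        intercept_nm2=float(intercept),
        fit_lags=idx,
        r2=r2,
        rss_nm4=rss,
        v_nm_s=float(np.sqrt(max(v2, 0.0))),
        clamped_D=bool(active[0]),
        clamped_v=bool(active[1]),
    )


def fit_lognormal(D_values, composition_label: str = "",
                  dmpc_fraction: float | None = None) -> EnsembleStats:
    """Maximum-likelihood log-normal fit to an ensemble of per-particle D.

    Zero or negative values cannot enter the log fit; they are excluded and
    counted in ``n_excluded``.  The arithmetic mean of the retained values
    is reported alongside (the quantity usually plotted as the
    per-composition average), together with the geometric mean
    ``exp(mu_log)``.
    """
    D = np.asarray(D_values, dtype=float)
    positive = D[np.isfinite(D) & (D > 0)]
    n_excluded = int(D.size - positive.size)
    if positive.size < 3:
        raise ValueError(
            f"log-normal fit needs >= 3 positive D values; got {positive.size}"
        )
    logD = np.log(positive)
    mu = float(logD.mean())
    sigma = float(logD.std(ddof=0))  # MLE
    return EnsembleStats(
        composition_label=composition_label,
        D_um2_s=positive,
        mu_log=mu,
        sigma_log=sigma,
        arithmetic_mean_D=float(positive.mean()),
        geometric_mean_D=float(np.exp(mu)),
        n_excluded=n_excluded,
        dmpc_fraction=dmpc_fraction,
    )


def composition_trend(ensembles: list, dmpc_fractions=None) -> dict:
    """Monotonicity of mean D across bilayer compositions.

    Returns the per-composition arithmetic means and a verdict
    ("decreasing", "increasing" or "none") from the sign of the Spearman
    rank correlation between mean D and DMPC fraction.
    """
    if dmpc_fractions is None:
        dmpc_fractions = [e.dmpc_fraction for e in ensembles]
    fractions = np.asarray(dmpc_fractions, dtype=float)
    means = np.array([e.arithmetic_mean_D for e in ensembles])
    report = {
        "dmpc_fraction": fractions.tolist(),
        "mean_D_um2_s": means.tolist(),
        "n_tracks": [e.n for e in ensembles],
    }
    if means.size < 2 or np.unique(fractions).size < 2:
        report.update(spearman_rho=None, verdict="none")  # None keeps JSON valid
        return report
    rho = stats.spearmanr(fractions, means).statistic
    if np.isnan(rho) or rho == 0:
        report.update(spearman_rho=None, verdict="none")
        return report
    verdict = "decreasing" if rho < 0 else "increasing"
    report.update(spearman_rho=float(rho), verdict=verdict)
    return report


def _minimal_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Map displacements into (−box/2, box/2] per axis (+box/2 at the tie)."""
    return box / 2.0 - np.mod(box / 2.0 - d, box)


def unwrap_periodic(series, box) -> np.ndarray:
    """Unwrap a periodic-boundary position series into continuous coordinates.

    Successive displacements are mapped to their minimal image per axis and
    cumulatively summed from the first point; a displacement of exactly half
    the box resolves to +box/2.  Used to turn wrapped centre-of-mass series
    from periodic simulation boxes into trajectories suitable for MSD
    analysis.
    """
    pos = np.atleast_2d(np.asarray(series, dtype=float))
    squeeze = np.asarray(series).ndim == 1
    if squeeze:
        pos = pos.T
    box = np.broadcast_to(np.asarray(box, dtype=float), (pos.shape[1],))
    if np.any(box <= 0):
        raise ValueError("box lengths must be positive")
    steps = _minimal_image(np.diff(pos, axis=0), box)
    out = np.vstack([pos[:1], pos[:1] + np.cumsum(steps, axis=0)])
    return out[:, 0] if squeeze else out


def wrap_periodic(series, box, center: float = 0.0) -> np.ndarray:
    """Wrap continuous coordinates back into a periodic box.

    With ``center=0`` values map to (−box/2, box/2]; with ``center=box/2``
    to (0, box].  Inverse of :func:`unwrap_periodic` up to box translations.
    """
    pos = np.asarray(series, dtype=float)
    box = np.asarray(box, dtype=float)
    return center + _minimal_image(pos - center, box)
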
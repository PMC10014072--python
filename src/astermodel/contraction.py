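"""Dynamics analyses: telescoping contraction and gliding-assay speeds.

A quasi-one-dimensional network connecting two asters contracts like a
series of identical units, each shortening at the same strain rate s, so
speed grows linearly with distance from the network center and the
maximum aster speed scales with the initial separation L as s·L/2. The
strain rate itself is set by the single-motor speed, so ratios of
max-speed-vs-L slopes between motors mirror ratios of gliding speeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import MergerExperiment, MotorSpec, VelocityProfile

__all__ = [
    "track_max_speed",
    "fit_velocity_profile",
    "merger_slope",
    "slope_speed_ratio_check",
    "gliding_speed",
]


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge shrinkage (min_periods = 1)."""
    if window <= 1:
        return x
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def track_max_speed(
    exp: MergerExperiment,
    smoothing_window: int = 5,
    early_window_s: float = 100.0,
) -> float:
    """Maximum aster speed during the early (elastic) contraction phase.

    Positions are smoothed with a centered moving average, speeds come
    from central differences (one-sided at the ends), and the maximum
    magnitude over both asters within the first ``early_window_s``
    seconds after the series start is returned. Only the initial
    contraction rate is meaningful: at later times motor unbinding and
    network rearrangement make the response viscous.
    """
    if len(exp.times) < 5:
        raise ValueError("need at least 5 time points")
    t0 = exp.times[0]
    sel = exp.times <= t0 + early_window_s
    if sel.sum() < 2:
        sel = np.zeros_like(sel, dtype=bool)
        sel[:2] = True
    speeds = []
    for pos in (exp.positions_a, exp.positions_b):
        # second-order edges: the maximum usually sits at t = 0, where a
        # first-order difference would bias fast contractions low
        v = np.gradient(_smooth(pos, smoothing_window), exp.times, edge_order=2)
        speeds.append(np.max(np.abs(v[sel])))
    return float(max(speeds))


def fit_velocity_profile(vp: VelocityProfile) -> tuple[float, float]:
    """Strain rate from a linear speed-vs-|x| fit through the origin.

    Returns ``(s, r2)``: the telescoping model predicts speed = s·|x|
    with the network center at x = 0, so the fit is constrained through
    the origin by symmetry. A markedly low r² indicates a non-telescoping
    (e.g. uniform) speed field.
    """
    x = np.abs(vp.x_positions)
    v = vp.mean_speeds
    if np.all(x == 0):
        raise ValueError("all positions at the network center: slope undefined")
    if not (np.any(vp.x_positions > 0) and np.any(vp.x_positions < 0)):
        raise ValueError("profile must span both sides of the network center")
    s = float((x @ v) / (x @ x))
    ss_res = float(np.sum((v - s * x) ** 2))
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return s, r2


def merger_slope(
    points: list,
    through_origin: bool = False,
) -> tuple[float, float]:
    """Slope of maximum merger speed vs initial aster separation.

    ``points`` is a sequence of (separation_L in μm, max_speed in μm/s).
    Returns ``(slope, intercept)`` in 1/s and μm/s; the default fit keeps
    a free intercept, ``through_origin=True`` constrains it to zero
    (the telescoping model predicts max_speed = s·L/2 exactly).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (separation, max_speed) points")
    L, vmax = pts[:, 0], pts[:, 1]
    if through_origin:
        return float((L @ vmax) / (L @ L)), 0.0
    slope, intercept = np.polyfit(L, vmax, 1)
    return float(slope), float(intercept)


def slope_speed_ratio_check(
    slopes: dict,
    motors: list[MotorSpec],
) -> pd.DataFrame:
    """Compare pairwise slope ratios with single-motor speed ratios.

    ``slopes`` maps motor name to its max-speed-vs-separation slope
    (1/s). Returns all ordered pairs with slope ratio, gliding-speed
    ratio and the relative discrepancy |slope_ratio/speed_ratio − 1|.
    Zero denominators are flagged with NaN ratios rather than raised.
    """
    if len(motors) < 2:
        raise ValueError("need at least 2 motors")
    by_name = {m.name: m for m in motors}
    rows = []
    for a in motors:
        for b in motors:
            if a.name == b.name:
                continue
            sa, sb = slopes[a.name], slopes[b.name]
            slope_ratio = sa / sb if sb != 0 else np.nan
            speed_ratio = by_name[a.name].speed_v / by_name[b.name].speed_v
            rows.append(
                {
                    "motor_a": a.name,
                    "motor_b": b.name,
                    "slope_ratio": slope_ratio,
                    "speed_ratio": speed_ratio,
                    "relative_discrepancy": abs(slope_ratio / speed_ratio - 1.0)
                    if np.isfinite(slope_ratio)
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)


def gliding_speed(
    tracks: list,
    stuck_threshold: float = 0.02,
    dt: float | None = None,
) -> tuple[float, int]:
    """Mean gliding speed over moving microtubule tracks.

    Each track is an (n, 2+) array of (t_s, x_um[, y_um]) samples; its
    speed is total path length over duration. Tracks slower than
    ``stuck_threshold`` (μm/s) are excluded — surface-pinned microtubules
    otherwise bias the mean low — and the exclusion count is reported.
    """
    speeds = []
    for tr in tracks:
        tr = np.asarray(tr, dtype=float)
        if tr.ndim != 2 or tr.shape[0] < 2:
            raise ValueError("each track needs >= 2 samples of (t, x[, y])")
        t = tr[:, 0]
        xy = tr[:, 1:]
        path = float(np.sum(np.linalg.norm(np.diff(xy, axis=0), axis=1)))
        duration = float(t[-1] - t[0])
        if duration <= 0:
            raise ValueError("track duration must be positive")
        speeds.append(path / duration)
    speeds = np.asarray(speeds)
    moving = speeds >= stuck_threshold
    n_excluded = int((~moving).sum())
    if not moving.any():
        raise ValueError("all tracks below the stuck threshold")
    return float(speeds[moving].mean()), n_excluded
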
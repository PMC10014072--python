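"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the experiments' data-generating processes: microtubule
radial profiles with a dense core plateau, an optional shoulder and an
inflection point; two-channel aster images rendered from the steady-state
motor model with per-wedge amplitude variation and multiplicative noise;
telescoping merger trajectories whose strain rate is proportional to the
single-motor speed; and gliding-assay tracks with a stuck fraction. All
randomness flows through a single seeded generator per call, so outputs
are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core_model import steady_state_motor_profile
from .types import (
    AsterImagePair,
    MergerExperiment,
    ModelParams,
    MotorSpec,
    RadialProfile,
)

__all__ = [
    "MtProfileSpec",
    "NoiseSpec",
    "make_mt_profile",
    "make_aster_image_pair",
    "AsterGroundTruth",
    "make_merger_set",
    "make_velocity_profile",
    "make_gliding_tracks",
]

_FAMILIES = ("exponential", "logistic_decay", "shoulder_plus_decay")


@dataclass(frozen=True)
class MtProfileSpec:
    """Parameters of a synthetic microtubule radial profile.

    The profile is ``background + amplitude·g(r)`` with g = 1 on the core
    plateau (r < ``core_plateau_r``) and the named decay family beyond
    it. When ``outer_radius_target`` is set, ``decay_scale`` is re-solved
    so the 2×background crossing sits exactly there. ``depletion_r``
    smoothly cuts the microtubule signal to zero beyond that radius,
    emulating the microtubule-depleted zone between an aster and the
    unactivated background region.
    """

    family: str = "exponential"
    amplitude: float = 1.0
    decay_scale: float = 20.0
    inflection_r: Optional[float] = None
    core_plateau_r: float = 15.0
    background: float = 0.0
    outer_radius_target: Optional[float] = None
    depletion_r: Optional[float] = None
    depletion_width: float = 3.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        if self.background < 0 or self.amplitude <= self.background:
            raise ValueError("need amplitude > background >= 0")
        if self.decay_scale <= 0 or self.core_plateau_r <= 0:
            raise ValueError("scales must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    """Pixel noise model: multiplicative or additive Gaussian."""

    model: str = "multiplicative_gaussian"
    sd_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("multiplicative_gaussian", "additive_gaussian"):
            raise ValueError("unknown noise model")
        if self.sd_fraction < 0:
            raise ValueError("sd_fraction must be >= 0")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # exp overflow in the far tail is benign (sigmoid -> 0) but noisy
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(z))


def _decay_shape(spec: MtProfileSpec, r: np.ndarray, decay_scale: float) -> np.ndarray:
    """Normalized decay g(r) with g(core_plateau_r) = 1, for r >= plateau."""
    cutoff = 1.0
    if spec.depletion_r is not None:
        cutoff = _sigmoid((r - spec.depletion_r) / spec.depletion_width)
    rc = spec.core_plateau_r
    if spec.family == "exponential":
        return cutoff * np.exp(-(r - rc) / decay_scale)
    if spec.family == "logistic_decay":
        r_infl = spec.inflection_r if spec.inflection_r is not None else rc + 2 * decay_scale
        sig = _sigmoid((r - r_infl) / decay_scale)
        sig0 = _sigmoid((rc - r_infl) / decay_scale)
        return cutoff * sig / sig0
    # shoulder_plus_decay: exponential modulated by a logistic shoulder —
    # both factors non-increasing, so the product stays monotone
    r_sh = spec.inflection_r if spec.inflection_r is not None else rc + decay_scale
    w = 0.25 * decay_scale
    shoulder = 1.0 + 1.5 * _sigmoid((r - r_sh) / w)
    shoulder0 = 1.0 + 1.5 * _sigmoid((rc - r_sh) / w)
    return cutoff * np.exp(-(r - rc) / decay_scale) * shoulder / shoulder0


def make_mt_profile(
    spec: MtProfileSpec, bin_width: float = 0.65, r_max: float = 120.0
) -> RadialProfile:
    """Deterministic synthetic microtubule profile on uniform bins.

    Constant plateau inside ``core_plateau_r``, then the decay family,
    approaching ``background`` at large r. With ``outer_radius_target``
    the decay scale is solved (closed form for the exponential family,
    bracketing root-find otherwise) so that the profile equals
    2×background exactly at the target radius.
    """
    edges = np.arange(int(np.ceil(r_max / bin_width)) + 1) * bin_width
    r = 0.5 * (edges[:-1] + edges[1:])
    rc = spec.core_plateau_r
    decay_scale = spec.decay_scale

    if spec.outer_radius_target is not None:
        rt = spec.outer_radius_target
        b, A = spec.background, spec.amplitude
        if b == 0:
            raise ValueError("outer_radius_target needs background > 0")
        g_target = b / A  # background + A·g = 2·background
        if not (0 < g_target < 1):
            raise ValueError("crossing target unreachable: need amplitude > background")
        if rt <= rc:
            raise ValueError("outer_radius_target must lie beyond the core plateau")
        if spec.family == "exponential" and spec.depletion_r is None:
            decay_scale = (rt - rc) / np.log(A / b)
        else:
            def gap(scale: float) -> float:
                return float(_decay_shape(spec, np.array([rt]), scale)[0]) - g_target

            decay_scale = brentq(gap, 1e-3, 10.0 * (rt - rc))

    values = np.where(
        r < rc,
        spec.amplitude,
        spec.amplitude * _decay_shape(spec, np.maximum(r, rc), decay_scale),
    )
    return RadialProfile(r, spec.background + values, channel="microtubule",
                         background=spec.background)


@dataclass
class AsterGroundTruth:
    """Everything a round-trip test needs to score an extraction or fit."""

    mt_profile: RadialProfile
    params: ModelParams
    wedge_factors: np.ndarray
    center_px: tuple
    pixel_size: float
    mt_background: float
    motor_profile: RadialProfile = field(default=None)  # type: ignore[assignment]

    def as_dict(self) -> dict:
        return {
            "Kd": self.params.Kd,
            "lambda0": self.params.lambda0,
            "C": self.params.C,
            "wedge_factors": list(map(float, self.wedge_factors)),
            "center_px": list(map(float, self.center_px)),
            "pixel_size_um": self.pixel_size,
            "mt_background": self.mt_background,
        }


def make_aster_image_pair(
    mt_profile: RadialProfile,
    params: ModelParams,
    wedge_factors: Sequence[float] | None = None,
    pixel_size: float = 0.65,
    image_size: int = 384,
    noise: NoiseSpec = NoiseSpec(sd_fraction=0.0),
    center_offset: tuple = (0.0, 0.0),
) -> tuple[AsterImagePair, AsterGroundTruth]:
    """Render a two-channel aster image from the steady-state model.

    The microtubule channel shows ``mt_profile`` (background included);
    the motor channel is the closed-form m_tot computed from the
    background-subtracted MT signal, scaled per 16-wedge sector by
    ``wedge_factors``. Pixels sample the radial curves linearly at their
    center's radius; noise is applied last. Returns the image pair and a
    ground-truth record for round-trip tests.
    """
    wedge_factors = np.ones(16) if wedge_factors is None else np.asarray(wedge_factors, float)
    n_wedges = wedge_factors.size
    if np.any(wedge_factors <= 0):
        raise ValueError("wedge factors must be positive")
    r_reach = mt_profile.r_centers[-1]
    half_extent = (image_size - 1) / 2 * pixel_size
    if half_extent > r_reach:
        raise ValueError(
            f"image half-extent {half_extent:.0f} um exceeds the profile reach "
            f"{r_reach:.0f} um; enlarge the profile or shrink the image"
        )

    signal = RadialProfile(
        mt_profile.r_centers,
        np.maximum(mt_profile.values - mt_profile.background, 0.0),
    )
    motor_true = steady_state_motor_profile(signal, params)

    cx = (image_size - 1) / 2 + center_offset[0]
    cy = (image_size - 1) / 2 + center_offset[1]
    ys, xs = np.indices((image_size, image_size))
    dx = (xs - cx) * pixel_size
    dy = (ys - cy) * pixel_size
    radii = np.hypot(dx, dy)
    angles = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    wedge_idx = np.minimum(
        (angles / (2 * np.pi / n_wedges)).astype(int), n_wedges - 1
    )

    mt_img = np.interp(radii, mt_profile.r_centers, mt_profile.values)
    motor_img = np.interp(radii, motor_true.r_centers, motor_true.values)
    motor_img = motor_img * wedge_factors[wedge_idx]

    rng = np.random.default_rng(noise.seed)
    if noise.sd_fraction > 0:
        if noise.model == "multiplicative_gaussian":
            mt_img = mt_img * (1.0 + noise.sd_fraction * rng.standard_normal(mt_img.shape))
            motor_img = motor_img * (1.0 + noise.sd_fraction * rng.standard_normal(motor_img.shape))
        else:
            scale_mt = noise.sd_fraction * mt_img.max()
            scale_mo = noise.sd_fraction * motor_img.max()
            mt_img = mt_img + scale_mt * rng.standard_normal(mt_img.shape)
            motor_img = motor_img + scale_mo * rng.standard_normal(motor_img.shape)
    mt_img = np.maximum(mt_img, 0.0)
    motor_img = np.maximum(motor_img, 0.0)

    pair = AsterImagePair(mt_img, motor_img, pixel_size=pixel_size)
    truth = AsterGroundTruth(
        mt_profile=mt_profile,
        params=params,
        wedge_factors=wedge_factors,
        center_px=(cx, cy),
        pixel_size=pixel_size,
        mt_background=mt_profile.background,
        motor_profile=motor_true,
    )
    return pair, truth


def make_merger_set(
    motor: MotorSpec,
    alpha: float = 0.04,
    separations: Sequence[float] = (200.0, 400.0, 600.0, 800.0, 1000.0),
    dt: float = 15.0,
    duration: float = 600.0,
    position_noise_sd: float = 0.0,
    seed: int = 0,
) -> list[MergerExperiment]:
    """Telescoping aster-merger trajectories for one motor.

    The network strain rate is s = alpha·v (alpha in 1/μm, v the motor's
    gliding speed in μm/s), encoding that the contraction rate is set by
    the single-motor speed. The default alpha of 0.04 /μm reproduces the
    measured max-speed-vs-separation slopes (s/2 ≈ 0.0023 1/s for Ncd,
    ≈0.0014 1/s for Kif11). Aster positions follow ±(L/2)·e^{−st} with
    optional Gaussian position noise; the default separations and 15 s
    cadence match the merger experimental design.
    """
    if duration < 5 * dt:
        raise ValueError("duration must cover at least 5 frames")
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    rng = np.random.default_rng(seed)
    s = alpha * motor.speed_um_s
    times = np.arange(0.0, duration + dt / 2, dt)
    out = []
    for L in separations:
        decay = (L / 2) * np.exp(-s * times)
        noise_a = position_noise_sd * rng.standard_normal(times.size)
        noise_b = position_noise_sd * rng.standard_normal(times.size)
        out.append(
            MergerExperiment(
                motor=motor.name,
                separation_L=float(L),
                times=times,
                positions_a=-decay + noise_a,
                positions_b=decay + noise_b,
            )
        )
    return out


def make_velocity_profile(
    strain_rate: float,
    network_length: float,
    n_points: int = 41,
    speed_noise_sd: float = 0.0,
    seed: int = 0,
):
    """Speed vs position samples from an ideal telescoping network.

    Material points at signed positions x obey dx/dt = −s·x, so the speed
    magnitude is s·|x|; optional Gaussian noise is added to the speeds.
    """
    from .types import VelocityProfile

    rng = np.random.default_rng(seed)
    x = np.linspace(-network_length / 2, network_length / 2, n_points)
    v = strain_rate * np.abs(x)
    if speed_noise_sd > 0:
        v = np.maximum(v + speed_noise_sd * rng.standard_normal(x.size), 0.0)
    return VelocityProfile(x, v)


def make_gliding_tracks(
    v: float,
    sd: float,
    stuck_fraction: float,
    n_tracks: int = 50,
    duration: float = 60.0,
    dt: float = 1.0,
    jitter_sd: float = 0.01,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Gliding-assay track table with a known stuck fraction.

    Moving microtubules advance along a random direction at a per-track
    speed ~ Normal(``v``, ``sd``) (μm/s) with small positional jitter;
    stuck ones jitter in place. Returns a tidy table
    (track_id, t_s, x_um, y_um) and a ground-truth dict with the per-track
    speeds and stuck labels. The number of stuck tracks is the rounded
    expectation, so small samples still carry the requested fraction.
    """
    if not (0.0 <= stuck_fraction <= 1.0):
        raise ValueError("stuck_fraction must lie in [0, 1]")
    if n_tracks < 1:
        raise ValueError("need at least one track")
    rng = np.random.default_rng(seed)
    n_stuck = int(round(stuck_fraction * n_tracks))
    stuck = np.zeros(n_tracks, dtype=bool)
    stuck[rng.choice(n_tracks, size=n_stuck, replace=False)] = True
    times = np.arange(0.0, duration + dt / 2, dt)
    rows = []
    true_speeds = np.zeros(n_tracks)
    for i in range(n_tracks):
        theta = rng.uniform(0, 2 * np.pi)
        speed = 0.0 if stuck[i] else max(rng.normal(v, sd), 0.05 * v)
        true_speeds[i] = speed
        x0, y0 = rng.uniform(0, 100, size=2)
        x = x0 + speed * np.cos(theta) * times + jitter_sd * rng.standard_normal(times.size)
        y = y0 + speed * np.sin(theta) * times + jitter_sd * rng.standard_normal(times.size)
        rows.append(
            pd.DataFrame({"track_id": i, "t_s": times, "x_um": x, "y_um": y})
        )
    table = pd.concat(rows, ignore_index=True)
    truth = {
        "speeds_um_s": true_speeds,
        "stuck": stuck,
        "n_stuck": int(n_stuck),
        "mean_moving_speed": float(true_speeds[~stuck].mean()) if n_stuck < n_tracks else 0.0,
    }
    return table, truth
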
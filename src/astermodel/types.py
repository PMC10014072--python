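"""Domain containers shared across the package.

Unit conventions: lengths in μm, times in s, speeds in μm/s internally
(helpers accept nm/s and convert once at the boundary), concentrations in
arbitrary fluorescence units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

STEP_SIZE_UM = 0.008  # one motor step along a microtubule, 8 nm


def nm_per_s_to_um_per_s(v_nm_s: float) -> float:
    """Convert a speed quoted in nm/s (the usual single-motor unit) to μm/s."""
    return float(v_nm_s) / 1000.0


@dataclass(frozen=True)
class MotorSpec:
    """Single-molecule properties of a kinesin motor.

    Parameters
    ----------
    name : str
        Label, e.g. ``"K401"``.
    speed_v : float
        Single-motor speed in nm/s (gliding-assay scale).
    processivity_steps : float
        Mean number of 8 nm steps before detaching; 0 encodes
        "not processive".
    direction : str
        ``"plus"`` or ``"minus"`` (microtubule end the motor walks toward).
    diffusion_D : float
        Free-motor diffusion coefficient in μm²/s.
    """

    name: str
    speed_v: float
    processivity_steps: float
    direction: str
    diffusion_D: float = 1.0

    def __post_init__(self) -> None:
        if self.speed_v <= 0:
            raise ValueError("speed_v must be positive")
        if self.processivity_steps < 0:
            raise ValueError("processivity_steps must be >= 0")
        if self.direction not in ("plus", "minus"):
            raise ValueError("direction must be 'plus' or 'minus'")
        if self.diffusion_D <= 0:
            raise ValueError("diffusion_D must be positive")

    @property
    def speed_um_s(self) -> float:
        return nm_per_s_to_um_per_s(self.speed_v)

    @property
    def run_length_um(self) -> float:
        """Mean run length v/koff = steps × 8 nm."""
        if self.processivity_steps == 0:
            raise ValueError(
                f"{self.name} is not processive; run length from step count "
                "is undefined"
            )
        return self.processivity_steps * STEP_SIZE_UM

    @property
    def koff(self) -> float:
        """Unbinding rate v/(8 nm × steps), in 1/s."""
        return self.speed_um_s / self.run_length_um


# The three motors used in the aster experiments. Speeds are gliding-assay
# values; processivities are literature step counts; Ncd is non-processive
# so its koff cannot be derived from a step count.
K401 = MotorSpec("K401", speed_v=600.0, processivity_steps=100, direction="plus")
NCD = MotorSpec("Ncd236", speed_v=115.0, processivity_steps=0, direction="minus")
KIF11 = MotorSpec("Kif11(513)", speed_v=70.0, processivity_steps=10, direction="plus")


@dataclass(frozen=True)
class ModelParams:
    """Effective parameters of the steady-state motor distribution.

    Kd = koff/kon is the microtubule concentration (in the MT channel's
    fluorescence units) at which bound and free motors are equal;
    lambda0 = D/v (μm) compares free diffusion with bound advection;
    C is the motor-channel concentration scale at the reference radius.
    """

    Kd: float
    lambda0: float
    C: float

    def __post_init__(self) -> None:
        if not (self.Kd > 0 and self.lambda0 > 0 and self.C > 0):
            raise ValueError("Kd, lambda0 and C must all be positive")


@dataclass(frozen=True)
class RateParams:
    """Microscopic rates of the two-state motor model.

    kon in 1/(concentration·s), koff in 1/s, D in μm²/s, v in μm/s.
    """

    kon: float
    koff: float
    D: float
    v: float

    def __post_init__(self) -> None:
        for name in ("kon", "koff", "D", "v"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def Kd(self) -> float:
        return self.koff / self.kon

    @property
    def lambda0(self) -> float:
        return self.D / self.v


@dataclass
class RadialProfile:
    """A binned radial concentration curve for one fluorescence channel.

    ``r_centers`` are uniformly spaced bin centers (μm, strictly
    increasing); ``values`` are per-bin concentrations in arbitrary
    fluorescence units, with NaN marking empty bins that downstream
    operations must skip.
    """

    r_centers: np.ndarray
    values: np.ndarray
    channel: str = "microtubule"
    background: float = 0.0

    def __post_init__(self) -> None:
        self.r_centers = np.asarray(self.r_centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.r_centers.ndim != 1 or self.r_centers.size < 2:
            raise ValueError("r_centers must be a 1-D array with >= 2 bins")
        if self.values.shape != self.r_centers.shape:
            raise ValueError("values and r_centers must have the same shape")
        dr = np.diff(self.r_centers)
        if np.any(dr <= 0):
            raise ValueError("r_centers must be strictly increasing")
        if not np.allclose(dr, dr[0], rtol=1e-6):
            raise ValueError("r_centers must be uniformly spaced")
        if self.r_centers[0] < 0:
            raise ValueError("radii must be non-negative")
        if np.nanmin(self.values) < -1e-12:
            raise ValueError("concentration values must be non-negative")
        if self.background < 0:
            raise ValueError("background must be non-negative")

    @property
    def bin_width(self) -> float:
        return float(self.r_centers[1] - self.r_centers[0])

    def same_bins(self, other: "RadialProfile") -> bool:
        return self.r_centers.shape == other.r_centers.shape and np.allclose(
            self.r_centers, other.r_centers
        )

    def restrict(self, r_min: float, r_max: float) -> "RadialProfile":
        """Return the sub-profile with r_min <= r <= r_max."""
        sel = (self.r_centers >= r_min) & (self.r_centers <= r_max)
        if sel.sum() < 2:
            raise ValueError("restriction leaves fewer than 2 bins")
        return RadialProfile(
            self.r_centers[sel], self.values[sel], self.channel, self.background
        )


@dataclass
class MtLengthDistribution:
    """Sampled microtubule lengths (μm) with their median."""

    lengths: np.ndarray
    median: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        if np.any(self.lengths <= 0):
            raise ValueError("lengths must be positive")
        sample_median = float(np.median(self.lengths))
        if self.median is None:
            self.median = sample_median
        elif not np.isclose(self.median, sample_median, rtol=0.05, atol=0.05):
            raise ValueError("stated median inconsistent with the sample")


@dataclass
class AsterImagePair:
    """Registered microtubule + motor images of one aster.

    ``pixel_size`` is μm per pixel; activation geometry (the illuminated
    disk that seeded the aster) is optional and only used to place the
    background annulus.
    """

    mt_image: np.ndarray
    motor_image: np.ndarray
    pixel_size: float
    activation_center: Optional[tuple] = None
    activation_diameter: Optional[float] = None

    def __post_init__(self) -> None:
        self.mt_image = np.asarray(self.mt_image, dtype=float)
        self.motor_image = np.asarray(self.motor_image, dtype=float)
        if self.mt_image.shape != self.motor_image.shape:
            raise ValueError("channel image shapes must match")
        if self.mt_image.ndim != 2:
            raise ValueError("images must be 2-D single planes")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.mt_image.min() < 0 or self.motor_image.min() < 0:
            raise ValueError("intensities must be non-negative")


@dataclass
class WedgeSet:
    """Per-angular-sector radial profiles for both channels.

    Wedge w covers angles [2πw/n, 2π(w+1)/n), counter-clockwise from the
    +x axis; the wedges partition the disk exactly.
    """

    n_wedges: int
    mt_profiles: list
    motor_profiles: list
    wedge_angles: np.ndarray

    def __post_init__(self) -> None:
        if self.n_wedges < 2:
            raise ValueError("need at least 2 wedges")
        if len(self.mt_profiles) != self.n_wedges or len(self.motor_profiles) != self.n_wedges:
            raise ValueError("one profile per wedge and channel required")


@dataclass
class FitResult:
    """Outcome of fitting the steady-state model to motor data."""

    params: ModelParams
    fit_domain: tuple
    mean_error: float
    converged: bool
    n_iterations: int = 0
    per_wedge_C: Optional[list] = None
    wedge_errors: Optional[list] = None
    equilibrium_consistent: bool = False
    model_curve: Optional[RadialProfile] = None


@dataclass
class MergerExperiment:
    """One aster-merger experiment: two asters pulled together along x.

    Positions are signed distances (μm) along the network axis; the
    standard experimental separations are 200–1000 μm but any positive
    value is valid.
    """

    motor: str
    separation_L: float
    times: np.ndarray
    positions_a: np.ndarray
    positions_b: np.ndarray
    max_speed: Optional[float] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions_a = np.asarray(self.positions_a, dtype=float)
        self.positions_b = np.asarray(self.positions_b, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(self.positions_a)) and np.all(np.isfinite(self.positions_b))):
            raise ValueError("positions must be finite")
        if self.separation_L <= 0:
            raise ValueError("separation must be positive")
        if not (len(self.times) == len(self.positions_a) == len(self.positions_b)):
            raise ValueError("time and position series lengths must match")


@dataclass
class VelocityProfile:
    """Mean contraction speed vs signed distance from the network center."""

    x_positions: np.ndarray
    mean_speeds: np.ndarray

    def __post_init__(self) -> None:
        self.x_positions = np.asarray(self.x_positions, dtype=float)
        self.mean_speeds = np.asarray(self.mean_speeds, dtype=float)
        if self.x_positions.shape != self.mean_speeds.shape:
            raise ValueError("x and speed arrays must have the same length")
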
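"""From two-channel aster images to radial concentration profiles.

Conventions (the raw images do not fix these, so the package does): pixel
centers sit at integer (row, col) coordinates; distances are converted to
μm through the pixel size; radial bins are half-open [kΔr, (k+1)Δr); wedge
w covers angles [2πw/n, 2π(w+1)/n) counter-clockwise from the +x axis,
half-open, so the wedges partition the disk exactly.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from scipy.stats import binned_statistic

from .types import AsterImagePair, RadialProfile, WedgeSet

__all__ = [
    "find_aster_center",
    "radial_profile",
    "wedge_profiles",
    "estimate_background",
    "aster_outer_radius",
    "NoAsterError",
    "BimodalImageWarning",
    "DegenerateAsterWarning",
]


class NoAsterError(ValueError):
    """The image has no dominant intensity peak."""


class BimodalImageWarning(UserWarning):
    """More than one comparable bright blob: the centroid lies between them."""


class DegenerateAsterWarning(UserWarning):
    """The size statistic is undefined for this profile."""


def find_aster_center(
    image: np.ndarray, smoothing_radius: float = 2.0, pixel_size: float = 1.0
) -> tuple[float, float]:
    """Locate the aster center as a subpixel (x, y) in pixel coordinates.

    The image is Gaussian-smoothed (``smoothing_radius`` in μm, converted
    to pixels), thresholded at its 99th percentile, and the
    intensity-weighted centroid of the bright pixels is returned.
    Deterministic; raises :class:`NoAsterError` on a flat image and warns
    with :class:`BimodalImageWarning` when two comparable blobs are found.
    """
    image = np.asarray(image, dtype=float)
    med = np.median(image)
    if image.max() <= 1.05 * med or image.max() == 0:
        raise NoAsterError("no dominant intensity peak (max <= 1.05 x median)")
    sigma_px = smoothing_radius / pixel_size
    smooth = ndimage.gaussian_filter(image, sigma_px)
    mask = smooth >= np.percentile(smooth, 99.0)
    labels, n = ndimage.label(mask)
    if n > 1:
        masses = ndimage.sum_labels(smooth, labels, index=np.arange(1, n + 1))
        masses = np.sort(masses)[::-1]
        if masses[1] > 0.25 * masses[0]:
            warnings.warn(
                "multiple comparable bright blobs; centroid lies between them",
                BimodalImageWarning,
                stacklevel=2,
            )
    weights = np.where(mask, smooth, 0.0)
    cy, cx = ndimage.center_of_mass(weights)
    return float(cx), float(cy)


def _pixel_radii_um(shape: tuple, center: tuple, pixel_size: float):
    ys, xs = np.indices(shape)
    dx = (xs - center[0]) * pixel_size
    dy = (ys - center[1]) * pixel_size
    return np.hypot(dx, dy), np.arctan2(dy, dx)


def radial_profile(
    image: np.ndarray,
    center: tuple,
    pixel_size: float,
    bin_width: float | None = None,
    r_max: float | None = None,
    statistic: str = "mean",
) -> RadialProfile:
    """Bin pixel intensities by distance from ``center``.

    ``bin_width`` and ``r_max`` are in μm; the default bin width is one
    pixel-equivalent. Each pixel is assigned by its center's distance,
    bins are half-open, and the per-bin ``statistic`` (mean or median) is
    taken. Empty bins hold NaN and must be skipped downstream. If
    ``r_max`` reaches beyond the image a truncation warning is emitted.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    image = np.asarray(image, dtype=float)
    if bin_width is None:
        bin_width = pixel_size
    radii, _ = _pixel_radii_um(image.shape, center, pixel_size)
    reach = radii.max()
    if r_max is None:
        r_max = reach
    if r_max > reach + bin_width:
        warnings.warn(
            f"r_max={r_max:.1f} um exceeds the image extent; profile truncated",
            UserWarning,
            stacklevel=2,
        )
        r_max = reach
    n_bins = int(np.ceil(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    sel = radii < edges[-1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # empty bins -> NaN
        values, _, _ = binned_statistic(
            radii[sel], image[sel], statistic=statistic, bins=edges
        )
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialProfile(centers, np.where(np.isnan(values), np.nan, values))


def wedge_profiles(
    pair: AsterImagePair,
    center: tuple,
    n_wedges: int = 16,
    bin_width: float | None = None,
    r_max: float | None = None,
    statistic: str = "mean",
) -> WedgeSet:
    """Radial profiles inside each angular wedge, per channel.

    The wedge pixel sets partition the disk exactly (half-open angular
    bins), so summed per-wedge pixel counts per radial bin reproduce the
    full-disk counts.
    """
    if n_wedges < 2:
        raise ValueError("need at least 2 wedges")
    if bin_width is None:
        bin_width = pair.pixel_size
    radii, angles = _pixel_radii_um(pair.mt_image.shape, center, pair.pixel_size)
    if r_max is None:
        r_max = radii.max()
    wedge_width = 2 * np.pi / n_wedges
    wedge_idx = np.floor(np.mod(angles, 2 * np.pi) / wedge_width).astype(int)
    wedge_idx = np.minimum(wedge_idx, n_wedges - 1)  # guard angle == 2π rounding

    mt_profiles, motor_profiles = [], []
    for w in range(n_wedges):
        mask = wedge_idx == w
        mt = _masked_radial(pair.mt_image, radii, mask, bin_width, r_max, statistic)
        mo = _masked_radial(pair.motor_image, radii, mask, bin_width, r_max, statistic)
        mt.channel, mo.channel = "microtubule", "motor"
        mt_profiles.append(mt)
        motor_profiles.append(mo)
    bounds = np.arange(n_wedges + 1) * wedge_width
    return WedgeSet(n_wedges, mt_profiles, motor_profiles, bounds)


def _masked_radial(image, radii, mask, bin_width, r_max, statistic) -> RadialProfile:
    n_bins = int(np.ceil(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    sel = mask & (radii < edges[-1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values, _, _ = binned_statistic(
            radii[sel], np.asarray(image, float)[sel], statistic=statistic, bins=edges
        )
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialProfile(centers, values)


def estimate_background(
    image: np.ndarray,
    center: tuple,
    pixel_size: float,
    annulus: tuple | None = None,
) -> float:
    """Median intensity in an annulus far outside the aster.

    ``annulus`` is (r_in, r_out) in μm; by default the outermost 10% of
    the image's radial reach is used (when activation geometry is known,
    pass r_in = activation radius + 50 μm instead). The median is robust
    to the occasional bundle or stray aster in the annulus.
    """
    image = np.asarray(image, dtype=float)
    radii, _ = _pixel_radii_um(image.shape, center, pixel_size)
    # reach along the axes, not the corners, so the annulus is complete
    edge_reach = min(
        center[0], center[1],
        image.shape[1] - 1 - center[0], image.shape[0] - 1 - center[1],
    ) * pixel_size
    if annulus is None:
        annulus = (0.9 * edge_reach, edge_reach)
    r_in, r_out = annulus
    if r_out <= r_in:
        raise ValueError("annulus r_out must exceed r_in")
    sel = (radii >= r_in) & (radii < r_out)
    if not np.any(sel):
        raise ValueError("annulus contains no pixels")
    return float(np.median(image[sel]))


def aster_outer_radius(
    profile: RadialProfile,
    background: float,
    r_core: float = 15.0,
) -> float:
    """Aster size: where the (median) MT profile falls to 2× background.

    Scanning outward from ``r_core`` (the disordered-core cutoff), the
    first radius where the profile drops to ≤ 2·background is returned,
    linearly interpolated between the straddling bins. Crossings are only
    sought before the profile's global minimum beyond the core, so the
    trailing rise back to the unactivated background level is ignored.
    Emits :class:`DegenerateAsterWarning` and returns ``r_core`` when the
    profile never exceeds the threshold.
    """
    if background <= 0:
        raise ValueError("background must be positive: the 2x threshold is degenerate")
    threshold = 2.0 * background
    r = profile.r_centers
    vals = profile.values
    sel = (r >= r_core) & ~np.isnan(vals)
    if sel.sum() < 2:
        raise ValueError("profile has fewer than 2 usable bins beyond r_core")
    r, vals = r[sel], vals[sel]
    i_min = int(np.nanargmin(vals))
    r, vals = r[: i_min + 1], vals[: i_min + 1]

    if np.all(vals <= threshold):
        warnings.warn(
            "profile entirely at or below 2x background beyond the core",
            DegenerateAsterWarning,
            stacklevel=2,
        )
        return float(r_core)

    below = vals <= threshold
    crossings = np.nonzero(~below[:-1] & below[1:])[0]
    if len(crossings) == 0:
        if below[0]:
            # starts below, rises above: no outward crossing exists
            warnings.warn(
                "profile below threshold at the core cutoff", DegenerateAsterWarning,
                stacklevel=2,
            )
            return float(r_core)
        warnings.warn(
            "profile stays above 2x background out to its minimum",
            DegenerateAsterWarning,
            stacklevel=2,
        )
        return float(r[-1])
    i = crossings[0]
    # linear interpolation between the straddling bins
    f = (vals[i] - threshold) / (vals[i] - vals[i + 1])
    return float(r[i] + f * (r[i + 1] - r[i]))
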
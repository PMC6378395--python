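"""Global background estimation and the 34-parameter ROI measurements.

Each segmented marker ROI is summarized by three parameter families measured
on the *unaltered* z-projected image:

* 14 *Signal* parameters: mean, median, mode, min, max, stdev, skewness and
  kurtosis of the pixel intensities, plus mean/median/mode/min/max/stdev each
  divided by a global background intensity (skewness and kurtosis are scale
  free and are not normalized);
* 14 *Morphology* parameters: perimeter, bounding-box width and height, the
  ``shape`` offset (distance between the brightness-weighted center of mass
  and the bounding-box center), best-fit ellipse major/minor/angle, bounding
  box aspect ratio (AR), roundness, circularity, solidity, and the max/min
  Feret (caliper) diameters with the max-Feret angle;
* 2 marker-level *Geometry* parameters: area and raw integrated density
  (the remaining four Geometry parameters -- pair distance, pair angle and
  the partner marker's area/integrated density -- live on candidate pairs).

The global background is the mode of the image intensity distribution (KDE
peak) over pixels at or above a floor of 8, below which pixels are treated
as empty space without tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .imaging import Roi

__all__ = [
    "FeatureVector",
    "SIGNAL_PARAMS",
    "MORPHOLOGY_PARAMS",
    "MARKER_GEOMETRY_PARAMS",
    "MARKER_PARAMS",
    "estimate_background",
    "measure_roi",
    "measure_rois",
]

SIGNAL_PARAMS = (
    "mean",
    "median",
    "mode",
    "min",
    "max",
    "stdev",
    "skewness",
    "kurtosis",
    "mean_bg",
    "median_bg",
    "mode_bg",
    "min_bg",
    "max_bg",
    "stdev_bg",
)
MORPHOLOGY_PARAMS = (
    "perimeter",
    "width",
    "height",
    "shape",
    "major",
    "minor",
    "angle",
    "AR",
    "round",
    "circularity",
    "solidity",
    "feret",
    "minferet",
    "feret_angle",
)
MARKER_GEOMETRY_PARAMS = ("area", "intden")
MARKER_PARAMS = SIGNAL_PARAMS + MORPHOLOGY_PARAMS + MARKER_GEOMETRY_PARAMS


@dataclass(frozen=True)
class FeatureVector:
    """The per-marker measurements of one ROI (units: px and raw intensity)."""

    roi_id: int
    xm: float
    ym: float
    mean: float
    median: float
    mode: float
    min: float
    max: float
    stdev: float
    skewness: float
    kurtosis: float
    mean_bg: float
    median_bg: float
    mode_bg: float
    min_bg: float
    max_bg: float
    stdev_bg: float
    perimeter: float
    width: float
    height: float
    shape: float
    major: float
    minor: float
    angle: float
    AR: float
    round: float
    circularity: float
    solidity: float
    feret: float
    minferet: float
    feret_angle: float
    area: float
    intden: float
    flagged: bool = False

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


class NoTissueError(ValueError):
    """Raised when no pixel reaches the tissue-intensity floor."""


def estimate_background(image: np.ndarray, min_intensity: float = 8.0) -> float:
    """Mode (KDE peak) of the intensity distribution over tissue pixels.

    Pixels below ``min_intensity`` are ignored as empty space. Raises
    :class:`NoTissueError` when nothing remains.
    """
    values = np.asarray(image, dtype=float).ravel()
    values = values[values >= min_intensity]
    if values.size == 0:
        raise NoTissueError(
            f"no tissue signal: no pixel at or above intensity {min_intensity}"
        )
    lo, hi = float(values.min()), float(values.max())
    if hi - lo < 1e-12:
        return lo
    # subsample for speed; the mode of a megapixel image is stable under this
    if values.size > 200_000:
        rng = np.random.default_rng(0)
        values = rng.choice(values, 200_000, replace=False)
    kde = stats.gaussian_kde(values)
    grid = np.linspace(lo, hi, 1024)
    return float(grid[np.argmax(kde(grid))])


# ---------------------------------------------------------------------------
# geometry helpers

def _pixel_corner_hull(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Convex hull vertices (x, y) of the union of unit pixel squares."""
    from scipy.spatial import ConvexHull

    # each pixel contributes its 4 corners
    xs = np.concatenate([cols, cols + 1, cols, cols + 1]).astype(float)
    ys = np.concatenate([rows, rows, rows + 1, rows + 1]).astype(float)
    pts = np.unique(np.column_stack([xs, ys]), axis=0)
    if len(pts) < 3:
        return pts
    hull = ConvexHull(pts)
    return pts[hull.vertices]


def _feret(hull: np.ndarray) -> tuple[float, float, float]:
    """Max/min caliper diameters and the max-caliper angle (deg vs +x)."""
    n = len(hull)
    if n == 1:
        return 1.0, 1.0, 0.0
    # max Feret: max pairwise distance between hull vertices
    d = hull[:, None, :] - hull[None, :, :]
    dist = np.hypot(d[..., 0], d[..., 1])
    i, j = np.unravel_index(np.argmax(dist), dist.shape)
    feret_max = float(dist[i, j])
    dx, dy = hull[j] - hull[i]
    angle = float(np.degrees(np.arctan2(dy, dx)))
    if angle >= 90.0:
        angle -= 180.0
    elif angle < -90.0:
        angle += 180.0
    if n == 2:
        return feret_max, 0.0, angle
    # min Feret: min over hull edges of the width perpendicular to the edge
    widths = []
    for k in range(n):
        p0, p1 = hull[k], hull[(k + 1) % n]
        edge = p1 - p0
        norm = np.hypot(*edge)
        if norm < 1e-12:
            continue
        normal = np.array([-edge[1], edge[0]]) / norm
        widths.append(float(np.abs((hull - p0) @ normal).max()))
    return feret_max, min(widths), angle


def _ellipse_params(rows: np.ndarray, cols: np.ndarray) -> tuple[float, float, float]:
    """Best-fit (equal second moments) ellipse major/minor axes and angle.

    Angle is the major-axis direction vs the +x axis, degrees in [-90, 90),
    measured with y pointing down (image convention).
    """
    x = cols.astype(float)
    y = rows.astype(float)
    mx, my = x.mean(), y.mean()
    # + 1/12: variance of the uniform distribution over a unit pixel
    u20 = ((x - mx) ** 2).mean() + 1.0 / 12.0
    u02 = ((y - my) ** 2).mean() + 1.0 / 12.0
    u11 = ((x - mx) * (y - my)).mean()
    common = np.sqrt((u20 - u02) ** 2 + 4 * u11**2)
    lam1 = (u20 + u02 + common) / 2.0
    lam2 = (u20 + u02 - common) / 2.0
    major = 4.0 * np.sqrt(max(lam1, 0.0))
    minor = 4.0 * np.sqrt(max(lam2, 0.0))
    if abs(u11) < 1e-12 and abs(u20 - u02) < 1e-12:
        theta = 0.0
    else:
        # y is the row axis (down); report the on-screen angle vs +x
        theta = 0.5 * np.degrees(np.arctan2(-2 * u11, u20 - u02))
    if theta >= 90.0:
        theta -= 180.0
    elif theta < -90.0:
        theta += 180.0
    return float(major), float(minor), float(theta)


def _roi_grid(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    r0, c0 = rows.min(), cols.min()
    grid = np.zeros((rows.max() - r0 + 3, cols.max() - c0 + 3), dtype=bool)
    grid[rows - r0 + 1, cols - c0 + 1] = True
    return grid


def _perimeter(rows: np.ndarray, cols: np.ndarray) -> float:
    """Boundary length via the 4-direction Crofton estimate, which keeps
    rasterized disks close to the analytic circumference."""
    from skimage.measure import perimeter_crofton

    return float(perimeter_crofton(_roi_grid(rows, cols), directions=4))


def _center_hull_area(rows: np.ndarray, cols: np.ndarray) -> float:
    """Convex-hull area of the pixel centers (region area for tiny ROIs)."""
    from scipy.spatial import ConvexHull, QhullError

    pts = np.column_stack([cols, rows]).astype(float)
    if len(pts) < 3:
        return float(len(pts))
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:  # collinear
        return float(len(pts))


def _mode_int(values: np.ndarray) -> float:
    """Most frequent integer-cast intensity; ties broken by the smallest."""
    ints = np.asarray(values, dtype=np.int64)
    uniq, counts = np.unique(ints, return_counts=True)
    return float(uniq[np.argmax(counts)])


def measure_roi(
    image: np.ndarray,
    roi: Roi,
    background: float,
    min_pixels: int = 2,
) -> FeatureVector:
    """Measure all marker-level parameters of ``roi`` on the unaltered image.

    ROIs smaller than ``min_pixels`` are measured but flagged (excluded from
    classification downstream). ``background`` must be positive; the six
    ``*_bg`` ratios divide the corresponding raw statistic by it.
    """
    if background <= 0:
        raise ValueError(f"background must be > 0, got {background}")
    image = np.asarray(image, dtype=float)
    rows, cols = roi.rows, roi.cols
    if rows.min() < 0 or cols.min() < 0 or rows.max() >= image.shape[0] or cols.max() >= image.shape[1]:
        raise ValueError("ROI extends outside the image")
    vals = image[rows, cols]

    mean = float(vals.mean())
    median = float(np.median(vals))
    mode = _mode_int(vals)
    vmin = float(vals.min())
    vmax = float(vals.max())
    stdev = float(vals.std(ddof=0))
    if stdev < 1e-12:
        skewness, kurtosis = 0.0, 0.0  # constant region: defined, not NaN
    else:
        skewness = float(stats.skew(vals, bias=True))
        kurtosis = float(stats.kurtosis(vals, fisher=True, bias=True))

    area = float(len(rows))
    intden = float(vals.sum())
    perim = _perimeter(rows, cols)
    width, height = float(roi.width), float(roi.height)
    shape = float(
        np.hypot(roi.xm - (roi.bx + width / 2.0), roi.ym - (roi.by + height / 2.0))
    )
    major, minor, angle = _ellipse_params(rows, cols)
    hull = _pixel_corner_hull(rows, cols)
    feret, minferet, feret_angle = _feret(hull)
    # hull of pixel centers; clipped at 1 to absorb digitization bias
    solidity = min(area / max(_center_hull_area(rows, cols), 1e-9), 1.0)
    # cap at 1: digitized small regions can overshoot the analytic bound
    circularity = min(4.0 * np.pi * area / perim**2, 1.0) if perim > 0 else 0.0
    roundness = float(4.0 * area / (np.pi * major**2)) if major > 0 else 0.0
    ar = width / height if height > 0 else 0.0

    return FeatureVector(
        roi_id=roi.id,
        xm=roi.xm,
        ym=roi.ym,
        mean=mean,
        median=median,
        mode=mode,
        min=vmin,
        max=vmax,
        stdev=stdev,
        skewness=skewness,
        kurtosis=kurtosis,
        mean_bg=mean / background,
        median_bg=median / background,
        mode_bg=mode / background,
        min_bg=vmin / background,
        max_bg=vmax / background,
        stdev_bg=stdev / background,
        perimeter=perim,
        width=width,
        height=height,
        shape=shape,
        major=major,
        minor=minor,
        angle=angle,
        AR=float(ar),
        round=roundness,
        circularity=circularity,
        solidity=solidity,
        feret=feret,
        minferet=minferet,
        feret_angle=feret_angle,
        area=area,
        intden=intden,
        flagged=len(rows) < min_pixels,
    )


def measure_rois(
    image: np.ndarray,
    rois: Sequence[Roi],
    background: float | None = None,
    channel: str = "",
    min_pixels: int = 2,
) -> pd.DataFrame:
    """Feature table: one row per ROI with the 30 marker-level columns."""
    if background is None:
        background = estimate_background(image)
    records = [measure_roi(image, r, background, min_pixels).as_dict() for r in rois]
    table = pd.DataFrame.from_records(records) if records else pd.DataFrame(
        columns=["roi_id", "xm", "ym", *MARKER_PARAMS, "flagged"]
    )
    table.insert(1, "channel", channel)
    return table
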
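"""Per-parameter probability densities: the likelihood machinery.

Class-conditional densities for each graphical parameter are estimated
non-parametrically: plain Gaussian-kernel KDE for unbounded parameters, and
boundary-corrected (reflection) KDE for parameters with hard support limits
so no probability mass leaks outside e.g. (0, inf) for areas or (0, 1] for
solidity. Pair geometry uses the parametric forms the training data supports:
a Gaussian for the synapse pre-post distance, a normalized second-order
polynomial (chance pairings of uniform points grow linearly in r, clustering
adds curvature) for the noise distance, a wrapped KDE for the synapse pair
angle, and a uniform density for the noise pair angle.

All densities are represented on an evaluation grid and interpolated
linearly, which makes them cheap to evaluate, exactly serializable, and
guaranteed non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ParameterDensity",
    "DegenerateSamplesError",
    "fit_kde",
    "fit_bounded",
    "fit_gaussian",
    "fit_quadratic",
    "uniform_density",
    "fit_wrapped_kde",
    "fit_pair_geometry",
    "LIKELIHOOD_FLOOR",
    "BOUNDED_SUPPORTS",
]

DensityKind = Literal["kde", "bounded_kde", "gaussian", "quadratic", "uniform", "wrapped_kde"]

#: floor applied to density evaluations before likelihood products, so a
#: single unseen value cannot zero a posterior (standard Naive Bayes smoothing)
LIKELIHOOD_FLOOR = 1e-12

#: hard supports for parameters with a clear boundary (bounded KDE);
#: parameters not listed use plain KDE
BOUNDED_SUPPORTS: dict[str, tuple[float, float]] = {
    "area": (0.0, np.inf),
    "intden": (0.0, np.inf),
    "perimeter": (0.0, np.inf),
    "width": (0.0, np.inf),
    "height": (0.0, np.inf),
    "major": (0.0, np.inf),
    "minor": (0.0, np.inf),
    "feret": (0.0, np.inf),
    "minferet": (0.0, np.inf),
    "shape": (0.0, np.inf),
    "stdev": (0.0, np.inf),
    "stdev_bg": (0.0, np.inf),
    "circularity": (0.0, 1.1),
    "solidity": (0.0, 1.0),
    "round": (0.0, 1.1),
    "angle": (-90.0, 90.0),
    "feret_angle": (-90.0, 90.0),
}


class DegenerateSamplesError(ValueError):
    """All samples identical (zero variance): no KDE bandwidth exists."""


@dataclass(frozen=True)
class ParameterDensity:
    """A fitted 1-D density, evaluable anywhere on the real line.

    ``grid``/``values`` hold the tabulated density; evaluation interpolates
    linearly and returns 0 outside the grid (for bounded kinds, outside the
    declared support). ``params`` keeps the parametric representation where
    one exists (mu/sigma for ``gaussian``, polynomial coefficients for
    ``quadratic``).
    """

    kind: DensityKind
    grid: np.ndarray
    values: np.ndarray
    support: tuple[float, float]
    n_samples: int
    params: dict = field(default_factory=dict)
    wrap_period: float | None = None

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.wrap_period is not None:
            lo = self.support[0]
            x = (x - lo) % self.wrap_period + lo
        out = np.interp(x, self.grid, self.values, left=0.0, right=0.0)
        lo, hi = self.support
        out = np.where((x < lo) | (x > hi), 0.0, out)
        return out

    def integral(self) -> float:
        return float(np.trapezoid(self.values, self.grid))

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "grid": self.grid.tolist(),
            "values": self.values.tolist(),
            "support": [float(self.support[0]), float(self.support[1])],
            "n_samples": self.n_samples,
            "params": {k: float(v) for k, v in self.params.items()},
            "wrap_period": self.wrap_period,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterDensity":
        return cls(
            kind=d["kind"],
            grid=np.asarray(d["grid"], dtype=float),
            values=np.asarray(d["values"], dtype=float),
            support=(float(d["support"][0]), float(d["support"][1])),
            n_samples=int(d["n_samples"]),
            params=dict(d.get("params", {})),
            wrap_period=d.get("wrap_period"),
        )


def _silverman_bw(samples: np.ndarray) -> float:
    n = len(samples)
    sd = samples.std(ddof=1)
    iqr = np.subtract(*np.percentile(samples, [75, 25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    return 0.9 * scale * n ** (-0.2)


def _check_samples(samples, min_samples: int, name: str) -> np.ndarray:
    samples = np.asarray(samples, dtype=float)
    samples = samples[np.isfinite(samples)]
    if len(samples) < min_samples:
        raise ValueError(
            f"parameter {name!r}: {len(samples)} samples, need at least {min_samples}"
        )
    if samples.std() <= 1e-12 * max(1.0, np.abs(samples).max()):
        raise DegenerateSamplesError(
            f"parameter {name!r}: all {len(samples)} samples identical "
            f"({samples[0]!r}); no density can be fitted"
        )
    return samples


def _grid_points(span: float, bw: float, minimum: int = 512, cap: int = 8192) -> int:
    """Enough grid points to resolve the kernel (step <= bw/3)."""
    if bw <= 0 or span <= 0:
        return minimum
    return int(np.clip(np.ceil(3.0 * span / bw), minimum, cap))


def fit_kde(
    samples: Sequence[float],
    bandwidth: float | None = None,
    min_samples: int = 30,
    name: str = "",
    grid_points: int = 512,
) -> ParameterDensity:
    """Gaussian-kernel KDE with Silverman's rule bandwidth by default."""
    samples = _check_samples(samples, min_samples, name)
    bw = bandwidth if bandwidth is not None else _silverman_bw(samples)
    lo = samples.min() - 5 * bw
    hi = samples.max() + 5 * bw
    grid = np.linspace(lo, hi, max(grid_points, _grid_points(hi - lo, bw)))
    kde = stats.gaussian_kde(samples, bw_method=bw / samples.std(ddof=1))
    values = np.clip(kde(grid), 0.0, None)
    return ParameterDensity(
        kind="kde",
        grid=grid,
        values=values,
        support=(-np.inf, np.inf),
        n_samples=len(samples),
        params={"bandwidth": bw},
    )


def fit_bounded(
    samples: Sequence[float],
    lower: float,
    upper: float,
    bandwidth: float | None = None,
    min_samples: int = 30,
    name: str = "",
    grid_points: int = 512,
) -> ParameterDensity:
    """Boundary-corrected KDE: reflect mass at each finite bound.

    All samples must lie in [lower, upper]; the density is identically zero
    outside.
    """
    samples = _check_samples(samples, min_samples, name)
    bad = samples[(samples < lower) | (samples > upper)]
    if bad.size:
        shown = ", ".join(f"{v:g}" for v in bad[:5])
        raise ValueError(
            f"parameter {name!r}: {bad.size} sample(s) outside "
            f"[{lower:g}, {upper:g}]: {shown}"
        )
    bw = bandwidth if bandwidth is not None else _silverman_bw(samples)
    kde = stats.gaussian_kde(samples, bw_method=bw / samples.std(ddof=1))
    glo = lower if np.isfinite(lower) else samples.min() - 5 * bw
    ghi = upper if np.isfinite(upper) else samples.max() + 5 * bw
    grid = np.linspace(glo, ghi, max(grid_points, _grid_points(ghi - glo, bw)))
    values = kde(grid)
    if np.isfinite(lower):
        values = values + kde(2 * lower - grid)
    if np.isfinite(upper):
        values = values + kde(2 * upper - grid)
    return ParameterDensity(
        kind="bounded_kde",
        grid=grid,
        values=np.clip(values, 0.0, None),
        support=(lower, upper),
        n_samples=len(samples),
        params={"bandwidth": bw},
    )


def fit_gaussian(samples: Sequence[float], name: str = "", min_samples: int = 2) -> ParameterDensity:
    """Parametric Gaussian fit (sample mean / SD)."""
    samples = _check_samples(samples, min_samples, name)
    mu = float(samples.mean())
    sigma = float(samples.std(ddof=1))
    grid = np.linspace(mu - 6 * sigma, mu + 6 * sigma, 512)
    values = stats.norm.pdf(grid, mu, sigma)
    return ParameterDensity(
        kind="gaussian",
        grid=grid,
        values=values,
        support=(-np.inf, np.inf),
        n_samples=len(samples),
        params={"mu": mu, "sigma": sigma},
    )


def fit_quadratic(
    samples: Sequence[float], lower: float, upper: float, name: str = ""
) -> ParameterDensity:
    """Normalized second-order polynomial density on [lower, upper].

    Fitted by least squares to a histogram density, clipped at zero and
    renormalized.
    """
    samples = _check_samples(samples, 4, name)
    nbins = max(8, min(40, len(samples) // 10))
    hist, edges = np.histogram(samples, bins=nbins, range=(lower, upper), density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    coeffs = np.polyfit(centers, hist, 2)
    grid = np.linspace(lower, upper, 512)
    values = np.clip(np.polyval(coeffs, grid), 0.0, None)
    norm = np.trapezoid(values, grid)
    if norm <= 0:
        raise ValueError(f"parameter {name!r}: degenerate quadratic fit")
    values = values / norm
    return ParameterDensity(
        kind="quadratic",
        grid=grid,
        values=values,
        support=(lower, upper),
        n_samples=len(samples),
        params={"c2": float(coeffs[0]), "c1": float(coeffs[1]), "c0": float(coeffs[2]), "norm": float(norm)},
    )


def uniform_density(lower: float, upper: float) -> ParameterDensity:
    """Uniform density on [lower, upper]."""
    grid = np.linspace(lower, upper, 8)
    values = np.full_like(grid, 1.0 / (upper - lower))
    return ParameterDensity(
        kind="uniform",
        grid=grid,
        values=values,
        support=(lower, upper),
        n_samples=0,
    )


def fit_wrapped_kde(
    samples: Sequence[float],
    lower: float = -180.0,
    upper: float = 180.0,
    bandwidth: float | None = None,
    min_samples: int = 30,
    name: str = "",
) -> ParameterDensity:
    """KDE on a periodic domain [lower, upper): replicate samples +- period."""
    samples = _check_samples(samples, min_samples, name)
    period = upper - lower
    wrapped = (samples - lower) % period + lower
    bw = bandwidth if bandwidth is not None else _silverman_bw(wrapped)
    aug = np.concatenate([wrapped - period, wrapped, wrapped + period])
    kde = stats.gaussian_kde(aug, bw_method=bw / aug.std(ddof=1))
    grid = np.linspace(lower, upper, max(720, _grid_points(period, bw)))
    values = np.clip(kde(grid) * 3.0, 0.0, None)  # 3 replicas share the mass
    return ParameterDensity(
        kind="wrapped_kde",
        grid=grid,
        values=values,
        support=(lower, upper),
        n_samples=len(samples),
        params={"bandwidth": bw},
        wrap_period=period,
    )


def fit_pair_geometry(
    distances: Sequence[float],
    angles: Sequence[float],
    cls: Literal["synapse", "noise"],
    max_dist: float = 1.2,
    min_pairs: int = 30,
) -> tuple[ParameterDensity, ParameterDensity]:
    """Fit the pair distance and pair angle densities for one class.

    Synapse pairs: Gaussian distance, wrapped-KDE angle. Noise pairs:
    normalized quadratic distance on [0, max_dist], uniform angle.
    Distances in um, angles in degrees on [-180, 180).
    """
    distances = np.asarray(distances, dtype=float)
    angles = np.asarray(angles, dtype=float)
    if len(distances) < min_pairs:
        raise ValueError(
            f"class {cls!r}: {len(distances)} pairs, need at least {min_pairs}"
        )
    if cls == "synapse":
        dist_density = fit_gaussian(distances, name="distance")
        angle_density = fit_wrapped_kde(angles, name="pair_angle")
    else:
        dist_density = fit_quadratic(distances, 0.0, max_dist, name="distance")
        angle_density = uniform_density(-180.0, 180.0)
    return dist_density, angle_density
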
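"""Naive Bayes synapse/noise and mature/immature classification.

A candidate synapse is a pre-synaptic / post-synaptic marker pair whose
brightness-weighted centroids lie within 1.2 um of each other. For each
candidate the classifier combines

* a spatial prior: the expected number of chance pairings in a local
  5 um x 5 um window, ``random_pairs = random_factor * rho_pre * rho_post``
  (densities per um^2, scaled to the window area), calibrated once by
  simulating uniform random marker fields; the synapse prior is 0.5 when
  ``random_pairs < 2`` and ``1 / random_pairs`` otherwise;
* class-conditional likelihoods: products of the per-parameter densities of
  the pre-marker features, the post-marker features, and (when the Geometry
  category is selected) the pair distance and pair angle densities,

into the posterior probability of being a synapse. Candidates with posterior
above 50% are called synapses.

Training follows the layer anatomy of the adult retina: markers inside a
manually drawn outer-plexiform-layer (OPL) mask define the *ideal synapse*
class, markers outside it the *ideal noise* class. The same machinery,
trained on two sets of already-called synapses from an immature and a mature
stage, yields per-synapse maturity log-likelihoods.

Pair angle convention: degrees of the pre->post vector versus the +x axis,
in [-180, 180), with y pointing down (image rows); "vertical" is +-90.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import logsumexp

from .densities import (
    BOUNDED_SUPPORTS,
    LIKELIHOOD_FLOOR,
    DegenerateSamplesError,
    ParameterDensity,
    fit_bounded,
    fit_kde,
    fit_pair_geometry,
)
from .features import MARKER_PARAMS, MORPHOLOGY_PARAMS, SIGNAL_PARAMS

__all__ = [
    "ClassModel",
    "PriorModel",
    "PARAMETER_CATEGORIES",
    "build_class_model",
    "build_maturity_model",
    "calibrate_random_factor",
    "pair_candidates",
    "estimate_prior",
    "score_candidates",
    "call_synapses",
    "score_maturity",
    "classify_scene",
]

MODEL_SCHEMA_VERSION = 1

#: marker-level parameters by category; the pair distance/angle densities are
#: part of "geometry" but live on the pair, not the marker
PARAMETER_CATEGORIES: dict[str, tuple[str, ...]] = {
    "signal": SIGNAL_PARAMS,
    "morphology": MORPHOLOGY_PARAMS,
    "geometry": ("area", "intden"),
}

Subset = Literal["all", "signal", "morphology", "geometry", "distance"]


# ---------------------------------------------------------------------------
# model containers

@dataclass
class ClassModel:
    """Per-parameter densities for two classes plus pair-geometry densities."""

    role: str
    classes: tuple[str, str]
    marker_densities: dict  # class -> marker ("pre"/"post") -> param -> ParameterDensity
    pair_densities: dict  # class -> {"distance": PD, "angle": PD}
    max_dist: float
    provenance: dict = field(default_factory=dict)
    degenerate_params: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.classes) != 2:
            raise ValueError("exactly two classes required")
        sets = {
            cls: frozenset(self.marker_densities[cls][m])
            for cls in self.classes
            for m in ("pre", "post")
        }
        if len(set(sets.values())) != 1:
            raise ValueError("parameter sets differ between classes/markers")

    @property
    def parameters(self) -> tuple[str, ...]:
        return tuple(sorted(self.marker_densities[self.classes[0]]["pre"]))

    def log_marker_likelihood(
        self, features: pd.DataFrame, marker: str, cls: str, params: Sequence[str]
    ) -> np.ndarray:
        """Sum of floored log densities over ``params`` for each feature row."""
        dens = self.marker_densities[cls][marker]
        total = np.zeros(len(features))
        for p in params:
            if p not in dens:
                raise KeyError(f"parameter {p!r} missing from model class {cls!r}")
            if p not in features.columns:
                raise KeyError(f"parameter {p!r} missing from feature table")
            total += np.log(np.maximum(dens[p](features[p].to_numpy()), LIKELIHOOD_FLOOR))
        return total

    def log_pair_likelihood(
        self, distances: np.ndarray, angles: np.ndarray, cls: str, include_angle: bool = True
    ) -> np.ndarray:
        d = self.pair_densities[cls]
        out = np.log(np.maximum(d["distance"](distances), LIKELIHOOD_FLOOR))
        if include_angle:
            out = out + np.log(np.maximum(d["angle"](angles), LIKELIHOOD_FLOOR))
        return out

    # -- serialization -----------------------------------------------------
    def to_json(self, path=None) -> str:
        doc = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "role": self.role,
            "classes": list(self.classes),
            "max_dist": self.max_dist,
            "provenance": self.provenance,
            "degenerate_params": self.degenerate_params,
            "marker_densities": {
                cls: {
                    m: {p: d.to_dict() for p, d in dd.items()}
                    for m, dd in mm.items()
                }
                for cls, mm in self.marker_densities.items()
            },
            "pair_densities": {
                cls: {k: d.to_dict() for k, d in dd.items()}
                for cls, dd in self.pair_densities.items()
            },
        }
        text = json.dumps(doc)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ClassModel":
        if hasattr(source, "read"):
            doc = json.load(source)
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema {doc.get('schema_version')}")
        return cls(
            role=doc["role"],
            classes=tuple(doc["classes"]),
            marker_densities={
                c: {
                    m: {p: ParameterDensity.from_dict(d) for p, d in dd.items()}
                    for m, dd in mm.items()
                }
                for c, mm in doc["marker_densities"].items()
            },
            pair_densities={
                c: {k: ParameterDensity.from_dict(d) for k, d in dd.items()}
                for c, dd in doc["pair_densities"].items()
            },
            max_dist=float(doc["max_dist"]),
            provenance=doc.get("provenance", {}),
            degenerate_params=doc.get("degenerate_params", []),
        )


@dataclass(frozen=True)
class PriorModel:
    """Spatial-prior calibration: chance-pair slope and window geometry."""

    random_factor: float
    max_dist: float = 1.2
    window: float = 5.0
    seed: int = 0
    n_reps: int = 0

    def __post_init__(self) -> None:
        if self.random_factor <= 0 and self.max_dist > 0:
            raise ValueError("random_factor must be > 0")
        if self.window <= 0:
            raise ValueError("window must be > 0")


# ---------------------------------------------------------------------------
# training

def _fit_param_density(
    samples: np.ndarray, param: str, min_samples: int, degenerate: list
) -> ParameterDensity:
    support = BOUNDED_SUPPORTS.get(param)
    try:
        if support is None:
            return fit_kde(samples, min_samples=min_samples, name=param)
        lo, hi = support
        # digitization can push e.g. circularity a hair past its nominal
        # ceiling on tiny regions; clip rather than reject
        clipped = np.clip(samples, lo, hi if np.isfinite(hi) else None)
        return fit_bounded(clipped, lo, hi, min_samples=min_samples, name=param)
    except DegenerateSamplesError:
        degenerate.append(param)
        v = float(np.asarray(samples, dtype=float)[0])
        sigma = max(abs(v) * 0.01, 1e-6)
        grid = np.linspace(v - 6 * sigma, v + 6 * sigma, 64)
        values = np.exp(-0.5 * ((grid - v) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
        return ParameterDensity(
            kind="gaussian",
            grid=grid,
            values=values,
            support=(-np.inf, np.inf),
            n_samples=len(samples),
            params={"mu": v, "sigma": sigma},
        )


def _usable(features: pd.DataFrame) -> pd.DataFrame:
    if "flagged" in features.columns:
        return features[~features["flagged"].astype(bool)]
    return features


def _pairs_within(
    pre: pd.DataFrame, post: pd.DataFrame, pixel_size: float, max_dist: float
) -> pd.DataFrame:
    """All cross-channel centroid pairs within ``max_dist`` um."""
    cols = ["pre_index", "post_index", "distance", "pair_angle"]
    if len(pre) == 0 or len(post) == 0:
        return pd.DataFrame(columns=cols)
    pre_xy = pre[["xm", "ym"]].to_numpy() * pixel_size
    post_xy = post[["xm", "ym"]].to_numpy() * pixel_size
    tree_pre = cKDTree(pre_xy)
    tree_post = cKDTree(post_xy)
    pairs = tree_pre.query_ball_tree(tree_post, r=max_dist)
    rec = []
    for i, js in enumerate(pairs):
        for j in js:
            dx, dy = post_xy[j] - pre_xy[i]
            rec.append((pre.index[i], post.index[j], float(np.hypot(dx, dy)),
                        float(np.degrees(np.arctan2(dy, dx)))))
    out = pd.DataFrame(rec, columns=cols)
    if len(out):
        out.loc[out["pair_angle"] >= 180.0, "pair_angle"] -= 360.0
    return out


def build_class_model(
    pre_features: pd.DataFrame,
    post_features: pd.DataFrame,
    in_mask: np.ndarray,
    pixel_size: float,
    role: str = "synapse_noise",
    max_dist: float = 1.2,
    min_rois: int = 30,
    min_pairs: int = 30,
    provenance: Mapping | None = None,
) -> ClassModel:
    """Train the synapse/noise model from masked feature tables.

    ``in_mask`` gives, per channel, a boolean vector aligned with the feature
    table rows: True for ROIs whose centroid lies inside the OPL mask
    (synapse class), False outside (noise class). Pass a tuple
    ``(in_mask_pre, in_mask_post)`` or a single concatenated pair.
    Pair-geometry densities per class are fitted from within-class pairs
    under the same ``max_dist`` rule.
    """
    if isinstance(in_mask, (tuple, list)):
        mask_pre, mask_post = (np.asarray(m, dtype=bool) for m in in_mask)
    else:
        raise TypeError("in_mask must be a (pre, post) pair of boolean vectors")
    pre_features = _usable(pre_features)
    post_features = _usable(post_features)
    mask_pre = mask_pre[pre_features.index]
    mask_post = mask_post[post_features.index]

    groups = {
        "synapse": (pre_features[mask_pre], post_features[mask_post]),
        "noise": (pre_features[~mask_pre], post_features[~mask_post]),
    }
    degenerate: list = []
    marker_densities: dict = {}
    pair_densities: dict = {}
    for cls, (pre_c, post_c) in groups.items():
        for name, table in (("pre", pre_c), ("post", post_c)):
            if len(table) < min_rois:
                raise ValueError(
                    f"class {cls!r} has only {len(table)} {name} ROIs "
                    f"(minimum {min_rois})"
                )
        marker_densities[cls] = {
            m: {
                p: _fit_param_density(
                    t[p].to_numpy(dtype=float), p, min_rois, degenerate
                )
                for p in MARKER_PARAMS
            }
            for m, t in (("pre", pre_c), ("post", post_c))
        }
        pairs = _pairs_within(pre_c, post_c, pixel_size, max_dist)
        if len(pairs) < min_pairs:
            raise ValueError(
                f"class {cls!r} has only {len(pairs)} pairs (minimum {min_pairs})"
            )
        dist_d, ang_d = fit_pair_geometry(
            pairs["distance"], pairs["pair_angle"],
            "synapse" if cls == "synapse" else "noise",
            max_dist=max_dist, min_pairs=min_pairs,
        )
        pair_densities[cls] = {"distance": dist_d, "angle": ang_d}

    return ClassModel(
        role=role,
        classes=("synapse", "noise"),
        marker_densities=marker_densities,
        pair_densities=pair_densities,
        max_dist=max_dist,
        provenance=dict(provenance or {}),
        degenerate_params=degenerate,
    )


def build_maturity_model(
    mature: Mapping[str, pd.DataFrame],
    immature: Mapping[str, pd.DataFrame],
    pixel_size: float,
    max_dist: float = 1.2,
    min_rois: int = 30,
    provenance: Mapping | None = None,
) -> ClassModel:
    """Train a mature/immature model from two sets of called synapses.

    Each input maps ``"pre"``/``"post"`` to the feature tables of the
    synapses' markers (row-aligned: row i of pre and post belong to the same
    synapse) and may include ``"pairs"``: a table with ``distance`` and
    ``pair_angle`` columns. Both pair-distance densities use the Gaussian
    synapse form (these are all synapses, merely of different maturity).
    """
    degenerate: list = []
    marker_densities: dict = {}
    pair_densities: dict = {}
    for cls, data in (("mature", mature), ("immature", immature)):
        marker_densities[cls] = {}
        for m in ("pre", "post"):
            table = _usable(data[m])
            if len(table) < min_rois:
                raise ValueError(
                    f"class {cls!r} has only {len(table)} {m} ROIs (minimum {min_rois})"
                )
            marker_densities[cls][m] = {
                p: _fit_param_density(
                    table[p].to_numpy(dtype=float), p, min_rois, degenerate
                )
                for p in MARKER_PARAMS
            }
        pairs = data.get("pairs")
        if pairs is None or len(pairs) < min_rois:
            raise ValueError(f"class {cls!r}: pair table with >= {min_rois} rows required")
        dist_d, ang_d = fit_pair_geometry(
            pairs["distance"], pairs["pair_angle"], "synapse", max_dist=max_dist
        )
        pair_densities[cls] = {"distance": dist_d, "angle": ang_d}
    return ClassModel(
        role="maturity",
        classes=("mature", "immature"),
        marker_densities=marker_densities,
        pair_densities=pair_densities,
        max_dist=max_dist,
        provenance=dict(provenance or {}),
        degenerate_params=degenerate,
    )


# ---------------------------------------------------------------------------
# spatial prior

def calibrate_random_factor(
    max_dist: float = 1.2,
    window: float = 5.0,
    n_reps: int = 20,
    seed: int = 0,
    side: float = 30.0,
    densities: Sequence[float] = (0.1, 0.2, 0.4, 0.8, 1.2),
) -> PriorModel:
    """Calibrate the chance-pair slope by simulating uniform marker fields.

    Two independent homogeneous point sets are thrown into a periodic square
    (side ``side`` um) over a grid of density combinations; the cross-pair
    count per unit area is regressed (through the origin) on the density
    product. For uniform points the expected slope is pi * max_dist^2.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    if max_dist == 0:
        return PriorModel(random_factor=0.0, max_dist=0.0, window=window,
                          seed=seed, n_reps=n_reps)
    rng = np.random.default_rng(seed)
    area = side * side
    xs, ys = [], []
    for _ in range(n_reps):
        for r1 in densities:
            for r2 in densities:
                n1 = rng.poisson(r1 * area)
                n2 = rng.poisson(r2 * area)
                if n1 == 0 or n2 == 0:
                    count = 0
                else:
                    p1 = rng.uniform(0, side, size=(n1, 2))
                    p2 = rng.uniform(0, side, size=(n2, 2))
                    t1 = cKDTree(p1, boxsize=side)
                    t2 = cKDTree(p2, boxsize=side)
                    count = t1.count_neighbors(t2, max_dist)
                xs.append((n1 / area) * (n2 / area))
                ys.append(count / area)
    x = np.asarray(xs)
    y = np.asarray(ys)
    slope = float((x * y).sum() / (x * x).sum())
    return PriorModel(random_factor=slope, max_dist=max_dist, window=window,
                      seed=seed, n_reps=n_reps)


# ---------------------------------------------------------------------------
# candidate scoring

def pair_candidates(
    pre_features: pd.DataFrame,
    post_features: pd.DataFrame,
    pixel_size: float,
    max_dist: float = 1.2,
) -> pd.DataFrame:
    """All pre/post centroid pairs within ``max_dist`` um.

    A marker may appear in multiple candidates. Returns a table with
    ``pre_index``/``post_index`` (row labels into the feature tables),
    ``distance`` (um) and ``pair_angle`` (deg).
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    return _pairs_within(_usable(pre_features), _usable(post_features), pixel_size, max_dist)


def estimate_prior(
    candidates: pd.DataFrame,
    pre_features: pd.DataFrame,
    post_features: pd.DataFrame,
    pixel_size: float,
    prior_model: PriorModel,
) -> pd.DataFrame:
    """Attach ``prior_synapse``/``prior_noise`` to each candidate.

    Local marker densities are counted in the ``window`` x ``window`` um
    square centered on the pair midpoint; ``random_pairs`` scales the density
    product by the calibrated slope and the window area.
    """
    out = candidates.copy()
    if len(out) == 0:
        out["prior_synapse"] = pd.Series(dtype=float)
        out["prior_noise"] = pd.Series(dtype=float)
        out["random_pairs"] = pd.Series(dtype=float)
        return out
    pre_xy = pre_features.loc[out["pre_index"], ["xm", "ym"]].to_numpy() * pixel_size
    post_xy = post_features.loc[out["post_index"], ["xm", "ym"]].to_numpy() * pixel_size
    mid = 0.5 * (pre_xy + post_xy)
    half = prior_model.window / 2.0
    all_pre = _usable(pre_features)[["xm", "ym"]].to_numpy() * pixel_size
    all_post = _usable(post_features)[["xm", "ym"]].to_numpy() * pixel_size
    # Chebyshev metric turns the ball query into a square window
    tp = cKDTree(all_pre)
    tq = cKDTree(all_post)
    n_pre = np.array([len(ix) for ix in tp.query_ball_point(mid, half, p=np.inf)])
    n_post = np.array([len(ix) for ix in tq.query_ball_point(mid, half, p=np.inf)])
    area = prior_model.window**2
    rho_pre = n_pre / area
    rho_post = n_post / area
    random_pairs = prior_model.random_factor * rho_pre * rho_post * area
    prior_s = np.where(random_pairs < 2.0, 0.5, 1.0 / np.maximum(random_pairs, 2.0))
    out["random_pairs"] = random_pairs
    out["prior_synapse"] = prior_s
    out["prior_noise"] = 1.0 - prior_s
    return out


def _subset_params(subset: Subset) -> tuple[tuple[str, ...], bool, bool]:
    """Marker parameters, and whether pair distance / pair angle are used."""
    if subset == "all":
        params = sum((PARAMETER_CATEGORIES[c] for c in ("signal", "morphology", "geometry")), ())
        return params, True, True
    if subset == "distance":
        return (), True, False
    if subset not in PARAMETER_CATEGORIES:
        raise ValueError(f"unknown parameter subset {subset!r}")
    params = PARAMETER_CATEGORIES[subset]
    use_pair = subset == "geometry"
    return params, use_pair, use_pair


def score_candidates(
    candidates: pd.DataFrame,
    pre_features: pd.DataFrame,
    post_features: pd.DataFrame,
    model: ClassModel,
    subset: Subset = "all",
) -> pd.DataFrame:
    """Fill likelihoods, evidence and posterior for each candidate.

    Per class, the log likelihood sums the selected pre-marker parameters,
    the selected post-marker parameters, and the pair distance (and angle)
    densities when the Geometry category (or the distance-only subset) is
    selected. The posterior combines them with the candidate's priors.
    """
    params, use_dist, use_angle = _subset_params(subset)
    out = candidates.copy()
    if len(out) == 0:
        for c in ("log_likelihood_synapse", "log_likelihood_noise", "evidence",
                  "posterior_synapse", "posterior_noise", "call"):
            out[c] = pd.Series(dtype=float)
        return out
    pre_rows = pre_features.loc[out["pre_index"]]
    post_rows = post_features.loc[out["post_index"]]
    dist = out["distance"].to_numpy(dtype=float)
    ang = out["pair_angle"].to_numpy(dtype=float)
    logL = {}
    for cls in model.classes:
        ll = model.log_marker_likelihood(pre_rows, "pre", cls, params)
        ll = ll + model.log_marker_likelihood(post_rows, "post", cls, params)
        if use_dist:
            ll = ll + model.log_pair_likelihood(dist, ang, cls, include_angle=use_angle)
        logL[cls] = ll
    c_pos, c_neg = model.classes
    if "prior_synapse" in out.columns:
        prior_pos = out["prior_synapse"].to_numpy(dtype=float)
    else:
        prior_pos = np.full(len(out), 0.5)
    log_post = np.log(prior_pos) + logL[c_pos]
    log_neg = np.log(1.0 - prior_pos) + logL[c_neg]
    evidence = logsumexp([log_post, log_neg], axis=0)
    posterior = np.exp(log_post - evidence)
    out[f"log_likelihood_{c_pos}"] = logL[c_pos]
    out[f"log_likelihood_{c_neg}"] = logL[c_neg]
    out["evidence"] = evidence
    out[f"posterior_{c_pos}"] = posterior
    out[f"posterior_{c_neg}"] = 1.0 - posterior
    out["call"] = np.where(posterior > 0.5, c_pos, c_neg)
    return out


def call_synapses(
    scored: pd.DataFrame,
    pre_features: pd.DataFrame,
    post_features: pd.DataFrame,
    pixel_size: float,
    threshold: float = 0.5,
    resolve: Literal["none", "one_to_one"] = "none",
) -> pd.DataFrame:
    """Keep candidates with posterior strictly above ``threshold``.

    With ``resolve="one_to_one"`` shared markers are resolved greedily by
    descending posterior. The synapse coordinate is the midpoint of the pre
    and post centroids (um).
    """
    kept = scored[scored["posterior_synapse"] > threshold].copy()
    kept = kept.sort_values("posterior_synapse", ascending=False, kind="mergesort")
    if resolve == "one_to_one":
        used_pre: set = set()
        used_post: set = set()
        keep_rows = []
        for idx, row in kept.iterrows():
            if row["pre_index"] in used_pre or row["post_index"] in used_post:
                continue
            used_pre.add(row["pre_index"])
            used_post.add(row["post_index"])
            keep_rows.append(idx)
        kept = kept.loc[keep_rows]
    if len(kept) == 0:
        kept["x_um"] = pd.Series(dtype=float)
        kept["y_um"] = pd.Series(dtype=float)
        return kept
    pre_xy = pre_features.loc[kept["pre_index"], ["xm", "ym"]].to_numpy() * pixel_size
    post_xy = post_features.loc[kept["post_index"], ["xm", "ym"]].to_numpy() * pixel_size
    mid = 0.5 * (pre_xy + post_xy)
    kept["x_um"] = mid[:, 0]
    kept["y_um"] = mid[:, 1]
    return kept.sort_index()


def score_maturity(
    synapses: pd.DataFrame,
    pre_features: pd.DataFrame,
    post_features: pd.DataFrame,
    model: ClassModel,
    subset: Subset = "all",
) -> pd.DataFrame:
    """Per-synapse, per-marker mature/immature log-likelihoods.

    Equal class priors; no hard call is made. Columns: ``pre_log_mature``,
    ``pre_log_immature``, ``post_log_mature``, ``post_log_immature`` plus the
    totals ``log_mature``/``log_immature`` (including pair geometry when the
    subset selects it).
    """
    if model.role != "maturity":
        raise ValueError(f"model role is {model.role!r}, expected 'maturity'")
    params, use_dist, use_angle = _subset_params(subset)
    out = synapses[[c for c in ("pre_index", "post_index", "distance", "pair_angle")
                    if c in synapses.columns]].copy()
    pre_rows = pre_features.loc[synapses["pre_index"]]
    post_rows = post_features.loc[synapses["post_index"]]
    for cls in model.classes:
        pre_ll = model.log_marker_likelihood(pre_rows, "pre", cls, params)
        post_ll = model.log_marker_likelihood(post_rows, "post", cls, params)
        total = pre_ll + post_ll
        if use_dist and "distance" in synapses.columns:
            total = total + model.log_pair_likelihood(
                synapses["distance"].to_numpy(dtype=float),
                synapses["pair_angle"].to_numpy(dtype=float),
                cls,
                include_angle=use_angle,
            )
        out[f"pre_log_{cls}"] = pre_ll
        out[f"post_log_{cls}"] = post_ll
        out[f"log_{cls}"] = total
    return out


def classify_scene(
    pre_features: pd.DataFrame,
    post_features: pd.DataFrame,
    model: ClassModel,
    prior_model: PriorModel,
    pixel_size: float,
    subset: Subset = "all",
    threshold: float = 0.5,
    resolve: Literal["none", "one_to_one"] = "none",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience end-to-end: pair, prior, score, call.

    Returns ``(scored_candidates, synapse_table)``.
    """
    cands = pair_candidates(pre_features, post_features, pixel_size, model.max_dist)
    cands = estimate_prior(cands, pre_features, post_features, pixel_size, prior_model)
    scored = score_candidates(cands, pre_features, post_features, model, subset)
    synapses = call_synapses(scored, pre_features, post_features, pixel_size,
                             threshold, resolve)
    return scored, synapses
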
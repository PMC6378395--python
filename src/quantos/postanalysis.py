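"""Average-synapse imaging, radial profiles, ROC evaluation and counting.

Detections are judged against ground-truth coordinates by greedy one-to-one
matching (nearest pair first) within 1 um; the resulting labels feed an
empirical ROC curve with a DeLong 95% confidence interval on the AUC.
Called synapses are visualized by cropping a 4.34 um square around each
pair midpoint, rotating so the pre->post axis points along +y, averaging
across synapses, and reducing each channel to a radial intensity profile
around its brightest maximum. Nuclei counting restricted to a mask supports
per-photoreceptor synapse normalization in transplant analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats

from .imaging import SegmentationConfig, extract_rois_dapi

__all__ = [
    "RocResult",
    "AverageSynapse",
    "match_ground_truth",
    "roc_auc",
    "average_synapse",
    "radial_profile",
    "count_photoreceptors",
    "likelihood_histogram_2d",
]


# ---------------------------------------------------------------------------
# ground-truth matching

def match_ground_truth(
    detections: np.ndarray,
    truth: np.ndarray,
    max_dist: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy nearest-first one-to-one matching within ``max_dist`` (um).

    Returns ``(labels, matched_truth)``: a boolean label per detection
    (True = matched a truth point) and a boolean per truth point (True =
    claimed by some detection); unmatched truths are misses.
    """
    detections = np.asarray(detections, dtype=float).reshape(-1, 2)
    truth = np.asarray(truth, dtype=float).reshape(-1, 2)
    labels = np.zeros(len(detections), dtype=bool)
    claimed = np.zeros(len(truth), dtype=bool)
    if len(detections) == 0 or len(truth) == 0:
        return labels, claimed
    diff = detections[:, None, :] - truth[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    cand = np.argwhere(dist <= max_dist)
    order = np.argsort(dist[cand[:, 0], cand[:, 1]], kind="stable")
    for i, j in cand[order]:
        if labels[i] or claimed[j]:
            continue
        labels[i] = True
        claimed[j] = True
    return labels, claimed


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong CI

@dataclass(frozen=True)
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    n_positive: int
    n_negative: int
    match_dist: float | None = None


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance (single-curve case)."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    all_ranks = _midranks(np.concatenate([pos, neg]))
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # structural components
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[bool],
    match_dist: float | None = None,
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> RocResult:
    """Empirical ROC over score thresholds with a 95% CI on the AUC.

    ``ci_method`` is "delong" (default) or "bootstrap".
    """
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    m = int(labels.sum())
    n = int((~labels).sum())
    if m == 0 or n == 0:
        raise ValueError(f"both classes required (positives={m}, negatives={n})")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc, var = _delong_variance(scores, labels)
    if ci_method == "delong":
        z = stats.norm.ppf(0.975)
        sd = np.sqrt(max(var, 0.0))
        lo, hi = auc - z * sd, auc + z * sd
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = np.arange(len(scores))
        boots = []
        for _ in range(n_boot):
            b = rng.choice(idx, len(idx), replace=True)
            if labels[b].all() or (~labels[b]).all():
                continue
            a, _ = _delong_variance(scores[b], labels[b])
            boots.append(a)
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return RocResult(
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        ci_low=float(np.clip(lo, 0.0, 1.0)),
        ci_high=float(np.clip(hi, 0.0, 1.0)),
        n_positive=m,
        n_negative=n,
        match_dist=match_dist,
    )


# ---------------------------------------------------------------------------
# average synapse

@dataclass(frozen=True)
class AverageSynapse:
    """Aligned mean crops per channel plus bookkeeping."""

    images: dict  # channel -> 2-D mean image
    n: int
    crop_um: float
    pixel_size: float
    skipped_border: int

    @property
    def side_px(self) -> int:
        return next(iter(self.images.values())).shape[0]


def _rotated_crop(
    image: np.ndarray,
    center_xy_px: tuple[float, float],
    angle_deg: float,
    side_px: int,
) -> np.ndarray | None:
    """Sample a square crop rotated so the pair axis maps onto +y.

    ``angle_deg`` is the pre->post angle in the source; the output grid is
    rotated by (angle - 90) so that direction becomes +y. Bilinear
    interpolation; returns None when the rotated footprint leaves the image.
    """
    cx, cy = center_xy_px
    half = (side_px - 1) / 2.0
    offs = np.arange(side_px) - half
    ox, oy = np.meshgrid(offs, offs)  # output x (cols), y (rows)
    phi = np.radians(angle_deg - 90.0)
    sx = cx + np.cos(phi) * ox - np.sin(phi) * oy
    sy = cy + np.sin(phi) * ox + np.cos(phi) * oy
    if (sx.min() < 0 or sy.min() < 0 or sx.max() > image.shape[1] - 1
            or sy.max() > image.shape[0] - 1):
        return None
    return ndi.map_coordinates(image, [sy, sx], order=1, mode="nearest")


def average_synapse(
    images: dict,
    synapses: pd.DataFrame,
    pixel_size: float,
    crop_um: float = 4.34,
) -> AverageSynapse:
    """Pixel-wise mean of aligned synapse crops per channel.

    ``images`` maps channel name -> 2-D z-projected image; ``synapses``
    needs ``x_um``/``y_um`` (pair midpoint) and ``pair_angle`` columns.
    Border synapses whose rotated crop leaves the image are skipped.
    """
    if len(synapses) == 0:
        raise ValueError("no synapses to average")
    side_px = int(round(crop_um / pixel_size))
    sums = {ch: np.zeros((side_px, side_px)) for ch in images}
    used = 0
    skipped = 0
    for _, row in synapses.iterrows():
        # continuous coordinates place pixel centers at index + 0.5
        cx = row["x_um"] / pixel_size - 0.5
        cy = row["y_um"] / pixel_size - 0.5
        ang = row["pair_angle"] if "pair_angle" in row else 90.0
        crops = {}
        ok = True
        for ch, img in images.items():
            c = _rotated_crop(np.asarray(img, dtype=float), (cx, cy), ang, side_px)
            if c is None:
                ok = False
                break
            crops[ch] = c
        if not ok:
            skipped += 1
            continue
        for ch, c in crops.items():
            sums[ch] += c
        used += 1
    if used == 0:
        raise ValueError(f"no usable synapses ({skipped} skipped at borders)")
    return AverageSynapse(
        images={ch: s / used for ch, s in sums.items()},
        n=used,
        crop_um=crop_um,
        pixel_size=pixel_size,
        skipped_border=skipped,
    )


def radial_profile(avg: AverageSynapse, channel: str) -> pd.DataFrame:
    """Mean intensity vs radial distance from the channel's brightest maximum.

    Bin r collects pixels with radial distance in [r, r+1) px. Errors on a
    flat image (no defined center).
    """
    img = avg.images[channel]
    if np.ptp(img) < 1e-12:
        raise ValueError(f"channel {channel!r} image is flat; center undefined")
    # brightest local maximum
    footprint = np.ones((3, 3), dtype=bool)
    local_max = (img == ndi.maximum_filter(img, footprint=footprint))
    ys, xs = np.nonzero(local_max)
    k = np.argmax(img[ys, xs])
    cy, cx = float(ys[k]), float(xs[k])
    yy, xx = np.indices(img.shape)
    r = np.hypot(yy - cy, xx - cx)
    bins = np.floor(r).astype(int)
    nbins = int(np.floor(np.hypot(*img.shape) / 2.0))
    counts = np.bincount(bins.ravel(), minlength=nbins)[:nbins]
    sums = np.bincount(bins.ravel(), weights=img.ravel(), minlength=nbins)[:nbins]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "r_px": np.arange(nbins),
            "r_um": np.arange(nbins) * avg.pixel_size,
            "mean_intensity": mean,
            "n_pixels": counts,
        }
    )


# ---------------------------------------------------------------------------
# photoreceptor counting

def count_photoreceptors(
    dapi_image: np.ndarray,
    mask: np.ndarray,
    cfg: SegmentationConfig | None = None,
    synapses_um: np.ndarray | None = None,
    pixel_size: float = 1.0,
) -> dict:
    """Count nuclei inside a graft/rosette mask.

    ``mask`` is a boolean image; nuclei ROIs whose centroid falls inside
    count. With ``synapses_um`` (N, 2) coordinates given, the companion
    ``synapses_per_photoreceptor`` is n synapses in mask / count (None and
    flagged when the count is zero).
    """
    mask = np.asarray(mask, dtype=bool)
    out = {"count": 0, "n_synapses_in_mask": None, "synapses_per_photoreceptor": None,
           "undefined": False}
    if not mask.any():
        return out
    rois = extract_rois_dapi(np.asarray(dapi_image, dtype=float), cfg)
    inside = [
        r for r in rois
        if mask[min(int(round(r.ym)), mask.shape[0] - 1),
                min(int(round(r.xm)), mask.shape[1] - 1)]
    ]
    out["count"] = len(inside)
    if synapses_um is not None:
        syn = np.asarray(synapses_um, dtype=float).reshape(-1, 2)
        px = np.clip((syn / pixel_size).astype(int), 0,
                     [mask.shape[1] - 1, mask.shape[0] - 1])
        n_in = int(mask[px[:, 1], px[:, 0]].sum())
        out["n_synapses_in_mask"] = n_in
        if len(inside) > 0:
            out["synapses_per_photoreceptor"] = n_in / len(inside)
        else:
            out["undefined"] = True
    return out


# ---------------------------------------------------------------------------
# 2-D likelihood histograms

def likelihood_histogram_2d(
    table: pd.DataFrame,
    x_col: str,
    y_col: str,
    bins: int = 50,
) -> dict:
    """Deterministic 2-D histogram of paired log-likelihood columns.

    Returns counts plus bin edges, suitable for CSV export and bitwise
    reproduction.
    """
    x = table[x_col].to_numpy(dtype=float)
    y = table[y_col].to_numpy(dtype=float)
    counts, xe, ye = np.histogram2d(x, y, bins=bins)
    return {"counts": counts, "x_edges": xe, "y_edges": ye,
            "x_col": x_col, "y_col": y_col}
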
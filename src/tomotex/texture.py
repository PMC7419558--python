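"""Second-order texture features over lattice ROIs of quantized slabs.

Thirteen features from three matrix families:

* GLCM (grey level co-occurrence): Correlation, Homogeneity, Energy, Entropy
  (log base 2), from symmetrized, normalized co-occurrence matrices at pixel
  separation ``d`` along 0/45/90/135 degrees, averaged over the four
  directions.
* NGTDM (neighborhood grey tone difference): Contrast, Coarseness, Busyness,
  Complexity, from per-level sums of absolute deviations between center
  pixels and their neighborhood means.
* RLM (run length): Short/Long Run Emphasis, Grey Level Nonuniformity, Run
  Length Nonuniformity, Run Percentage, from maximal-run counts per
  direction, averaged over the four directions.

Grey levels are stored 0-based; formulas that use the absolute grey value
(NGTDM weighting, GLCM moments) evaluate it 1-based so that level 0 carries
weight.  Shift-invariant features are unaffected by this convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage

from tomotex.errors import DegenerateInputError, ParameterError
from tomotex.recon import SlabImage

ANGLES = (0, 45, 90, 135)

#: Canonical order of the 13 per-ROI features.
FEATURE_NAMES = (
    "glcm_correlation",
    "glcm_homogeneity",
    "glcm_energy",
    "glcm_entropy",
    "ngtdm_contrast",
    "ngtdm_coarseness",
    "ngtdm_busyness",
    "ngtdm_complexity",
    "rlm_sre",
    "rlm_lre",
    "rlm_gln",
    "rlm_rln",
    "rlm_rp",
)

_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass
class QuantizedROI:
    """Square tile of integer grey levels in [0, levels-1]."""

    pixels: np.ndarray
    levels: int = 256
    origin: tuple = (0, 0)  # (row, col) of the tile in the slab
    side_mm: Optional[float] = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 2:
            raise ParameterError("ROI must be 2D with side >= 2")
        if self.pixels.min() < 0 or self.pixels.max() >= self.levels:
            raise ParameterError("ROI grey values must lie in [0, levels-1]")

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


@dataclass
class GLCM:
    matrix: np.ndarray  # (levels, levels), normalized, symmetric
    d: int
    angle: int
    levels: int


@dataclass
class NGTDMResult:
    D: np.ndarray  # per-level difference sums
    p: np.ndarray  # per-level occurrence probabilities among center pixels
    n: int  # neighborhood radius
    n_centers: int
    levels: int

    @property
    def n_grey(self) -> int:
        return int(np.count_nonzero(self.p))


@dataclass
class RLM:
    matrix: np.ndarray  # (levels, max_run) integer run counts
    angle: int
    n_pixels: int

    @property
    def n_runs(self) -> int:
        return int(self.matrix.sum())


# ---------------------------------------------------------------------------
# Quantization and lattice tiling


def quantize(
    image: Union[SlabImage, np.ndarray],
    levels: int = 256,
    mask: Optional[np.ndarray] = None,
    range_quantiles: Optional[tuple] = None,
) -> np.ndarray:
    """Linear min-max binning into ``levels`` integer grey levels.

    The range is taken over the breast mask when one is available; a constant
    image maps to level 0 everywhere.  Monotone and invariant to positive
    affine rescaling of the input.  ``range_quantiles`` (e.g. ``(1, 99)``)
    switches to a robust percentile range with clipping — useful on small
    reconstructions where a few extreme artifact pixels would otherwise
    stretch the binning range.
    """
    if levels < 2:
        raise ParameterError(f"levels must be >= 2; got {levels}")
    if isinstance(image, SlabImage):
        mask = image.breast_mask if mask is None else mask
        image = image.pixels
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ParameterError("image must be finite-valued")
    ref = image[mask] if mask is not None else image
    if range_quantiles is not None:
        lo, hi = (float(v) for v in np.percentile(ref, range_quantiles))
    else:
        lo, hi = float(ref.min()), float(ref.max())
    if hi <= lo:
        return np.zeros(image.shape, dtype=np.int32)
    q = np.floor((image - lo) / (hi - lo) * levels).astype(np.int32)
    return np.clip(q, 0, levels - 1)


def roi_physical_side_mm(side_px: int, pixel_size_mm: float) -> float:
    """Physical ROI edge length for a given tile side in pixels."""
    return side_px * pixel_size_mm


def lattice_rois(
    slab: SlabImage,
    side: int = 35,
    levels: int = 256,
    quantized: Optional[np.ndarray] = None,
    range_quantiles: Optional[tuple] = None,
) -> list:
    """Tile the breast region into non-overlapping ``side``-pixel lattice ROIs.

    Tiles are anchored at the origin of the mask bounding box, row-major;
    only tiles lying fully inside the breast mask are kept.
    """
    mask = np.asarray(slab.breast_mask, dtype=bool)
    if not mask.any():
        raise DegenerateInputError("slab has an empty breast mask")
    if quantized is None:
        quantized = quantize(slab, levels=levels, range_quantiles=range_quantiles)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1

    rois = []
    for r in range(r0, r1 - side + 1, side):
        for c in range(c0, c1 - side + 1, side):
            if mask[r : r + side, c : c + side].all():
                rois.append(
                    QuantizedROI(
                        pixels=quantized[r : r + side, c : c + side],
                        levels=levels,
                        origin=(r, c),
                        side_mm=roi_physical_side_mm(side, slab.pixel_size_mm),
                    )
                )
    if not rois:
        warnings.warn("no complete lattice tile fits inside the breast mask", stacklevel=2)
    return rois


# ---------------------------------------------------------------------------
# GLCM


def compute_glcm(roi: QuantizedROI, d: int = 1, angle: int = 0) -> GLCM:
    """Symmetrized, normalized co-occurrence matrix at separation ``d``."""
    if d < 1:
        raise ParameterError(f"d must be >= 1; got {d}")
    if d >= roi.side:
        raise ParameterError(f"d={d} does not fit in a {roi.side}-pixel ROI")
    if angle not in _OFFSETS:
        raise ParameterError(f"angle must be one of {ANGLES}; got {angle}")
    dr, dc = (o * d for o in _OFFSETS[angle])
    img = roi.pixels
    h, w = img.shape
    r_lo, r_hi = max(0, -dr), min(h, h - dr)
    c_lo, c_hi = max(0, -dc), min(w, w - dc)
    a = img[r_lo:r_hi, c_lo:c_hi].ravel()
    b = img[r_lo + dr : r_hi + dr, c_lo + dc : c_hi + dc].ravel()
    lv = roi.levels
    counts = np.bincount(a * lv + b, minlength=lv * lv).reshape(lv, lv).astype(float)
    counts += counts.T  # count each pair in both orders
    total = counts.sum()
    if total == 0:
        raise DegenerateInputError("ROI has no pixel pairs at this displacement")
    return GLCM(matrix=counts / total, d=d, angle=angle, levels=lv)


def _glcm_stats(g: np.ndarray) -> dict:
    lv = g.shape[0]
    i = np.arange(1, lv + 1, dtype=float)
    px = g.sum(axis=1)
    py = g.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    var_x = float(((i - mu_x) ** 2) @ px)
    var_y = float(((i - mu_y) ** 2) @ py)
    return {"mu_x": mu_x, "mu_y": mu_y, "sigma_x": math.sqrt(var_x), "sigma_y": math.sqrt(var_y)}


def glcm_features(glcm: Union[GLCM, Sequence[GLCM]]) -> dict:
    """Correlation, Homogeneity, Energy, Entropy; mean over direction matrices.

    Correlation of a zero-variance matrix is undefined and reported as NaN;
    directions with undefined correlation are excluded from the average.
    """
    glcms = [glcm] if isinstance(glcm, GLCM) else list(glcm)
    per_dir = []
    for gl in glcms:
        g = gl.matrix
        lv = gl.levels
        idx = np.arange(1, lv + 1, dtype=float)
        stats = _glcm_stats(g)
        if stats["sigma_x"] * stats["sigma_y"] > 0:
            corr = (float(idx @ g @ idx) - stats["mu_x"] * stats["mu_y"]) / (
                stats["sigma_x"] * stats["sigma_y"]
            )
        else:
            corr = float("nan")
        absdiff = np.abs(idx[:, None] - idx[None, :])
        homog = float((g / (1.0 + absdiff)).sum())
        energy = float((g * g).sum())
        nz = g[g > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        per_dir.append(
            {
                "glcm_correlation": corr,
                "glcm_homogeneity": homog,
                "glcm_energy": energy,
                "glcm_entropy": entropy,
            }
        )
    out = {}
    for name in ("glcm_correlation", "glcm_homogeneity", "glcm_energy", "glcm_entropy"):
        vals = np.array([d[name] for d in per_dir])
        finite = vals[np.isfinite(vals)]
        out[name] = float(finite.mean()) if finite.size else float("nan")
    return out


# ---------------------------------------------------------------------------
# NGTDM


def compute_ngtdm(roi: QuantizedROI, n: int = 1) -> NGTDMResult:
    """Grey-tone difference sums over center pixels with full neighborhoods."""
    if n < 1:
        raise ParameterError(f"n must be >= 1; got {n}")
    if roi.side <= 2 * n:
        raise ParameterError(f"ROI side {roi.side} must exceed 2n = {2 * n}")
    img = roi.pixels.astype(float)
    size = 2 * n + 1
    win_sum = ndimage.uniform_filter(img, size=size, mode="constant") * size * size
    neigh_mean = (win_sum - img) / (size * size - 1)
    centers = (slice(n, img.shape[0] - n), slice(n, img.shape[1] - n))
    levels_c = roi.pixels[centers].ravel()
    dev = np.abs(img[centers] - neigh_mean[centers]).ravel()
    d_vec = np.bincount(levels_c, weights=dev, minlength=roi.levels)
    counts = np.bincount(levels_c, minlength=roi.levels)
    n_centers = levels_c.size
    return NGTDMResult(D=d_vec, p=counts / n_centers, n=n, n_centers=n_centers, levels=roi.levels)


def ngtdm_features(res: NGTDMResult, coarseness_eps: float = 1e-12) -> dict:
    """Contrast, Coarseness, Busyness, Complexity (sums over levels with p>0)."""
    if res.n_centers < 1:
        raise DegenerateInputError("NGTDM has no center pixels")
    present = res.p > 0
    i = (np.arange(res.levels, dtype=float) + 1.0)[present]  # 1-based grey value
    p = res.p[present]
    d = res.D[present]
    ng = i.size
    n2 = float(res.n_centers)

    pd_sum = float(p @ d)
    coarseness = 1.0 / (pd_sum + coarseness_eps)

    if ng < 2:
        contrast = 0.0
        complexity = 0.0
        busyness = float("nan")
    else:
        diff = i[:, None] - i[None, :]
        pp = p[:, None] * p[None, :]
        contrast = float((pp * diff**2).sum() / (ng * (ng - 1)) * d.sum() / n2)
        ipi = i * p
        denom = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
        busyness = pd_sum / denom if denom > 0 else float("nan")
        pdi = p * d
        complexity = float(
            (np.abs(diff) / (n2 * (p[:, None] + p[None, :])) * (pdi[:, None] + pdi[None, :])).sum()
        )
    return {
        "ngtdm_contrast": contrast,
        "ngtdm_coarseness": coarseness,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
    }


# ---------------------------------------------------------------------------
# RLM


def _lines(img: np.ndarray, angle: int) -> Iterable[np.ndarray]:
    h, w = img.shape
    if angle == 0:
        yield from img
    elif angle == 90:
        yield from img.T
    elif angle == 135:
        for k in range(-h + 1, w):
            yield np.diagonal(img, offset=k)
    elif angle == 45:
        flipped = img[:, ::-1]
        for k in range(-h + 1, w):
            yield np.diagonal(flipped, offset=k)
    else:
        raise ParameterError(f"angle must be one of {ANGLES}; got {angle}")


def compute_rlm(roi: QuantizedROI, angle: int = 0) -> RLM:
    """Counts of maximal same-level runs per scan line along ``angle``."""
    img = roi.pixels
    max_run = max(img.shape)
    r = np.zeros((roi.levels, max_run), dtype=np.int64)
    for line in _lines(img, angle):
        if line.size == 0:
            continue
        change = np.flatnonzero(np.diff(line)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [line.size]])
        lengths = ends - starts
        np.add.at(r, (line[starts], lengths - 1), 1)
    return RLM(matrix=r, angle=angle, n_pixels=int(img.size))


def _rlm_features_single(rlm: RLM) -> dict:
    r = rlm.matrix.astype(float)
    n = r.sum()
    if n == 0:
        raise DegenerateInputError("RLM has no runs")
    j = np.arange(1, r.shape[1] + 1, dtype=float)
    run_per_len = r.sum(axis=0)
    run_per_lvl = r.sum(axis=1)
    return {
        "rlm_sre": float((run_per_len / j**2).sum() / n),
        "rlm_lre": float((run_per_len * j**2).sum() / n),
        "rlm_gln": float((run_per_lvl**2).sum() / n),
        "rlm_rln": float((run_per_len**2).sum() / n),
        "rlm_rp": float(n / rlm.n_pixels),
    }


def rlm_features(rlms: Sequence[RLM]) -> dict:
    """Five run-length statistics, averaged across the direction matrices."""
    per_dir = [_rlm_features_single(r) for r in rlms]
    return {
        name: float(np.mean([d[name] for d in per_dir]))
        for name in ("rlm_sre", "rlm_lre", "rlm_gln", "rlm_rln", "rlm_rp")
    }


# ---------------------------------------------------------------------------
# Per-ROI and per-condition aggregation


def feature_vector(roi: QuantizedROI, d: int = 1, n: int = 1) -> dict:
    """All 13 named features for one ROI (directional families averaged)."""
    out = {}
    out.update(glcm_features([compute_glcm(roi, d=d, angle=a) for a in ANGLES]))
    out.update(ngtdm_features(compute_ngtdm(roi, n=n)))
    out.update(rlm_features([compute_rlm(roi, angle=a) for a in ANGLES]))
    return {name: out[name] for name in FEATURE_NAMES}


def _roi_overlaps_lesion(roi: QuantizedROI, slab: SlabImage, radius_px: float) -> bool:
    if not slab.truth_present or slab.truth_center is None:
        return False
    r0, c0 = roi.origin
    s = roi.side
    tr, tc = slab.truth_center
    nearest_r = min(max(tr, r0), r0 + s - 1)
    nearest_c = min(max(tc, c0), c0 + s - 1)
    return (nearest_r - tr) ** 2 + (nearest_c - tc) ** 2 <= radius_px**2


def roi_feature_frame(
    slabs: Sequence[SlabImage],
    side: int = 35,
    levels: int = 256,
    d: int = 1,
    n: int = 1,
    exclude_lesion_rois: bool = False,
    lesion_radius_px: float = 15.0,
    range_quantiles: Optional[tuple] = None,
) -> pd.DataFrame:
    """One row per lattice ROI with its 13 features and slab bookkeeping."""
    rows = []
    for slab in slabs:
        cond = dict(slab.condition)
        rois = lattice_rois(slab, side=side, levels=levels, range_quantiles=range_quantiles)
        for k, roi in enumerate(rois):
            if exclude_lesion_rois and _roi_overlaps_lesion(roi, slab, lesion_radius_px):
                continue
            row = {
                "condition": condition_key(cond),
                "slab_index": slab.slab_index,
                "truth_present": slab.truth_present,
                "roi_index": k,
                "roi_row": roi.origin[0],
                "roi_col": roi.origin[1],
            }
            row.update(cond)
            row.update(feature_vector(roi, d=d, n=n))
            rows.append(row)
    return pd.DataFrame(rows)


def condition_key(condition: dict) -> str:
    """Canonical string key for a condition dict (sorted field order)."""
    return "|".join(f"{k}={condition[k]}" for k in sorted(condition))


def condition_feature_table(
    slabs_by_condition: dict,
    side: int = 35,
    levels: int = 256,
    d: int = 1,
    n: int = 1,
    exclude_lesion_rois: bool = False,
) -> pd.DataFrame:
    """Per-condition mean/SD of each feature over all ROIs of all slabs.

    Lesion-present and lesion-absent slabs are pooled.  Conditions with no
    complete ROI are reported with n_roi = 0 and missing statistics rather
    than dropped.
    """
    records = []
    for cond, slabs in slabs_by_condition.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            df = roi_feature_frame(
                slabs, side=side, levels=levels, d=d, n=n, exclude_lesion_rois=exclude_lesion_rois
            )
        rec = {"condition": cond, "n_roi": len(df)}
        for name in FEATURE_NAMES:
            if len(df):
                rec[f"{name}_mean"] = df[name].mean(skipna=True)
                rec[f"{name}_sd"] = df[name].std(skipna=True, ddof=1) if len(df) > 1 else 0.0
            else:
                rec[f"{name}_mean"] = float("nan")
                rec[f"{name}_sd"] = float("nan")
        records.append(rec)
    return pd.DataFrame(records)
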
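"""Bead-aggregation assay quantification.

Brightfield images of antibody-conjugated microbeads are preprocessed
(center crop, sharpen, percentile contrast stretch with identical
settings across a batch), thresholded, and the areas of the resulting
bead aggregates are measured, categorized into five successive size
ranges, and summed per range.  Replicate reports are combined into
per-condition mean +/- s.d. summaries.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import convolve2d

from .config import BEAD_PIXEL_SIZE_UM, DEFAULT_BIN_EDGES_UM2
from .imaging import _otsu_threshold

__all__ = [
    "AggregateReport",
    "preprocess_bead_image",
    "detect_aggregates",
    "bin_aggregates",
    "compare_conditions",
]

# 3x3 sharpen kernel (center 12, edges/corners -1, normalized by 4)
_SHARPEN = np.array([[-1, -1, -1], [-1, 12, -1], [-1, -1, -1]], dtype=float) / 4.0


@dataclass
class AggregateReport:
    """Per-image summed aggregate areas over five size ranges (µm²)."""

    bin_edges_um2: tuple[float, ...]
    bin_sums_um2: np.ndarray
    n_aggregates: int
    image_id: str = ""
    condition: str = ""
    config_hash: str = ""

    def __post_init__(self) -> None:
        self.bin_sums_um2 = np.asarray(self.bin_sums_um2, dtype=float)
        if len(self.bin_edges_um2) != 5:
            raise ValueError("exactly 5 bin edges (defining 5 ranges) required")
        if len(self.bin_sums_um2) != 5:
            raise ValueError("exactly 5 bin sums required")
        if np.any(np.diff(self.bin_edges_um2) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.bin_sums_um2 < 0):
            raise ValueError("bin sums must be >= 0")

    @property
    def total_area_um2(self) -> float:
        return float(self.bin_sums_um2.sum())


def _settings_hash(settings: dict) -> str:
    return hashlib.sha256(
        json.dumps(settings, sort_keys=True).encode()
    ).hexdigest()[:12]


def preprocess_bead_image(image: np.ndarray, crop_px: int = 2000,
                          sharpen: bool = True,
                          contrast_saturation: float = 0.35,
                          ) -> tuple[np.ndarray, str]:
    """Center-crop, sharpen and contrast-stretch one assay image.

    Returns the processed image and a hash of the settings used; a batch
    runner must refuse to mix images processed with different hashes (the
    assay requires identical settings across conditions).
    ``contrast_saturation`` is the percent of pixels saturated at each
    tail of the intensity histogram by the linear stretch.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:  # color input: ITU-R 601 luminance
        img = img[..., 0] * 0.299 + img[..., 1] * 0.587 + img[..., 2] * 0.114
    h, w = img.shape
    if h < crop_px or w < crop_px:
        raise ValueError(f"image {img.shape} smaller than crop {crop_px}")
    r0 = (h - crop_px) // 2
    c0 = (w - crop_px) // 2
    img = img[r0:r0 + crop_px, c0:c0 + crop_px]
    if sharpen:
        img = convolve2d(img, _SHARPEN, mode="same", boundary="symm")
    lo, hi = np.percentile(img, [contrast_saturation, 100.0 - contrast_saturation])
    if hi > lo:
        img = np.clip((img - lo) / (hi - lo), 0.0, 1.0) * 255.0
    settings = {"crop_px": crop_px, "sharpen": sharpen,
                "contrast_saturation": contrast_saturation}
    return img, _settings_hash(settings)


def detect_aggregates(image: np.ndarray,
                      pixel_size_um: float = BEAD_PIXEL_SIZE_UM,
                      threshold_method: str = "otsu",
                      threshold: float | None = None,
                      min_area_um2: float = 0.0) -> list[tuple[int, float]]:
    """Threshold (dark beads on bright background) and measure aggregates.

    Default threshold is Otsu on the inverted brightfield image; 8-connected
    components below ``min_area_um2`` are dropped.  Returns (id, area_um2)
    pairs.  A constant (blank or saturated) image yields no detections.
    """
    if not pixel_size_um > 0:
        raise ValueError("pixel_size_um must be > 0")
    img = np.asarray(image, dtype=float)
    inv = img.max() - img
    if np.ptp(inv) == 0:
        warnings.warn("blank image: no aggregates detectable")
        return []
    if threshold_method == "otsu":
        thr = _otsu_threshold(inv)
    elif threshold_method == "fixed":
        if threshold is None:
            raise ValueError("fixed threshold_method requires threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    mask = inv > thr
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    areas_px = ndimage.sum_labels(np.ones_like(labels), labels,
                                  index=np.arange(1, n + 1))
    out = []
    oid = 0
    for a in areas_px:
        area = float(a) * pixel_size_um ** 2
        if area >= min_area_um2 and a > 0:
            out.append((oid, area))
            oid += 1
    return out


def bin_aggregates(detections: list[tuple[int, float]],
                   bin_edges_um2: tuple[float, ...] = DEFAULT_BIN_EDGES_UM2,
                   image_id: str = "", condition: str = "",
                   config_hash: str = "") -> AggregateReport:
    """Categorize aggregates into five successive size ranges and sum areas.

    Edges (e0..e4) define the half-open ranges [e0,e1), [e1,e2), [e2,e3),
    [e3,e4) and [e4, inf); every detected aggregate with area >= e0 falls
    in exactly one range, so the bin sums partition the total area.
    """
    edges = tuple(float(e) for e in bin_edges_um2)
    if len(edges) != 5:
        raise ValueError("exactly 5 edges required (five successive ranges)")
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    sums = np.zeros(5)
    n = 0
    for _oid, area in detections:
        if area < edges[0]:
            continue
        idx = int(np.searchsorted(edges, area, side="right")) - 1
        sums[idx] += area
        n += 1
    return AggregateReport(edges, sums, n, image_id=image_id,
                           condition=condition, config_hash=config_hash)


def compare_conditions(reports: list[AggregateReport]) -> pd.DataFrame:
    """Mean +/- sample s.d. of per-bin sums across replicates, per condition.

    Single-replicate groups report s.d. 0 with ``single_replicate=True``.
    All reports must share bin edges and preprocessing settings hash.
    """
    if not reports:
        raise ValueError("no reports to summarize")
    edges = reports[0].bin_edges_um2
    hashes = {r.config_hash for r in reports if r.config_hash}
    if len(hashes) > 1:
        raise ValueError("reports mix preprocessing settings "
                         f"(hashes {sorted(hashes)}); the assay requires "
                         "identical settings")
    for r in reports:
        if r.bin_edges_um2 != edges:
            raise ValueError("reports mix bin edges")
    rows = []
    conditions: dict[str, list[AggregateReport]] = {}
    for r in reports:
        conditions.setdefault(r.condition, []).append(r)
    for cond, reps in conditions.items():
        stack = np.stack([r.bin_sums_um2 for r in reps])
        mean = stack.mean(axis=0)
        sd = stack.std(axis=0, ddof=1) if len(reps) > 1 else np.zeros(5)
        for b in range(5):
            rows.append({
                "condition": cond,
                "bin": b,
                "bin_lower_um2": edges[b],
                "mean_sum_um2": float(mean[b]),
                "sd_sum_um2": float(sd[b]),
                "n_replicates": len(reps),
                "single_replicate": len(reps) == 1,
            })
    return pd.DataFrame(rows)
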
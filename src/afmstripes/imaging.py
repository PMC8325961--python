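"""Calibrated height-map I/O and preprocessing.

The central container is :class:`HeightMap`: a 2D field of heights in nm
with a lateral calibration in nm/pixel.  Preprocessing mirrors a typical
AFM workflow: impulse/speckle removal (median then mean filtering),
background subtraction so heights are relative to the mica surface,
min-max normalization for display, and binarization for object detection.

Coordinate convention: row-major arrays, origin at the top-left pixel,
``x`` = column index, ``y`` = row index, 0-based; physical position of
pixel ``(r, c)`` is ``(c * pixel_size_nm, r * pixel_size_nm)``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "HeightMap",
    "BinaryMask",
    "NormalizedImage",
    "read_image",
    "write_image",
    "denoise",
    "subtract_background",
    "normalize_height",
    "binarize",
]


@dataclass
class HeightMap:
    """A calibrated 2D height field (nm heights, nm/pixel laterally)."""

    values: np.ndarray
    pixel_size_nm: float
    frame_id: int | None = None
    acquisition_interval_s: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("HeightMap requires a non-empty 2D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("HeightMap heights must be finite")
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray) -> "HeightMap":
        """New map with the same calibration/metadata, different heights."""
        return replace(self, values=np.asarray(values, dtype=float),
                       meta=dict(self.meta))


@dataclass
class BinaryMask:
    """Boolean object mask with inherited calibration and threshold provenance."""

    values: np.ndarray
    pixel_size_nm: float
    provenance: dict

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("BinaryMask requires a 2D array")
        if not self.provenance or "method" not in self.provenance:
            raise ValueError("BinaryMask provenance must record the method used")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class NormalizedImage:
    """Unit-interval image plus the (min, max) nm range used, so the
    display mapping is invertible."""

    values: np.ndarray
    vmin_nm: float
    vmax_nm: float

    def to_nm(self) -> np.ndarray:
        return self.values * (self.vmax_nm - self.vmin_nm) + self.vmin_nm


def read_image(path: str | Path, pixel_size_nm: float,
               height_scale_nm: float | None = None) -> HeightMap:
    """Read a single-channel TIFF/PNG/BMP as a calibrated height map.

    Float TIFFs are taken to store heights in nm directly.  Integer
    formats require ``height_scale_nm``, the height in nm that the
    full-scale gray level maps to (gray 0 maps to 0 nm; the mapping is
    linear, e.g. 10 nm full scale on 8-bit data maps gray 255 to 10 nm).
    """
    path = Path(path)
    if pixel_size_nm is None or not pixel_size_nm > 0:
        raise ValueError("pixel_size_nm calibration is required (no silent default)")
    if path.suffix.lower() in {".tif", ".tiff"}:
        raw = tifffile.imread(path)
    else:
        raw = iio.imread(path)
    raw = np.asarray(raw)
    if raw.ndim == 3:
        raise ValueError(
            f"{path.name} has {raw.shape[-1]} channels; select a single "
            "channel (e.g. arr[..., 0]) before constructing a HeightMap"
        )
    if np.issubdtype(raw.dtype, np.floating):
        values = raw.astype(float)
    else:
        if height_scale_nm is None:
            raise ValueError(
                "integer image requires height_scale_nm (nm at full-scale gray)"
            )
        full_scale = np.iinfo(raw.dtype).max
        values = raw.astype(float) * (height_scale_nm / full_scale)
    return HeightMap(values, pixel_size_nm=pixel_size_nm,
                     meta={"source": str(path)})


def write_image(hm: HeightMap, path: str | Path) -> Path:
    """Write a height map as 32-bit float TIFF (heights in nm, lossless)."""
    path = Path(path)
    tifffile.imwrite(path, hm.values.astype(np.float32))
    return path


def _check_odd(name: str, size: int) -> None:
    if size < 1 or size % 2 == 0:
        raise ValueError(f"{name} must be an odd integer >= 1, got {size}")


def denoise(hm: HeightMap, median_size: int = 3, mean_size: int = 3) -> HeightMap:
    """Median filter then mean filter, reflection-padded; size 1 = identity."""
    _check_odd("median_size", median_size)
    _check_odd("mean_size", mean_size)
    out = hm.values
    if median_size > 1:
        out = ndimage.median_filter(out, size=median_size, mode="reflect")
    if mean_size > 1:
        out = ndimage.uniform_filter(out, size=mean_size, mode="reflect")
    res = hm.with_values(out)
    res.meta["denoise"] = {"median_size": median_size, "mean_size": mean_size}
    return res


def subtract_background(hm: HeightMap, method: str = "plane",
                        low_quantile: float = 0.20) -> HeightMap:
    """Subtract the substrate background so it centers on 0 nm.

    ``plane``
        Least-squares plane fitted to the pixels at or below the
        ``low_quantile`` height quantile (robust to the molecules, which
        occupy the upper tail), then subtracted.
    ``offset``
        Modal background height (histogram mode of the lower half of the
        height range) subtracted.

    A constant input has no defined background; it returns an all-zero
    map and sets ``meta['background']['degenerate']``.
    """
    if method not in {"plane", "offset"}:
        raise ValueError(f"unknown background method {method!r}")
    v = hm.values
    if np.ptp(v) == 0:
        warnings.warn("constant image: background undefined, returning zeros")
        res = hm.with_values(np.zeros_like(v))
        res.meta["background"] = {"method": method, "degenerate": True}
        return res
    if method == "plane":
        cutoff = np.quantile(v, low_quantile)
        sel = v <= cutoff
        rr, cc = np.nonzero(sel)
        A = np.column_stack([cc, rr, np.ones(rr.size)])
        coef, *_ = np.linalg.lstsq(A, v[sel], rcond=None)
        cols, rows = np.meshgrid(np.arange(v.shape[1]), np.arange(v.shape[0]))
        bg = coef[0] * cols + coef[1] * rows + coef[2]
        out = v - bg
        prov = {"method": "plane", "coef": [float(c) for c in coef],
                "low_quantile": low_quantile}
    else:
        lower = v[v <= np.quantile(v, 0.5)]
        hist, edges = np.histogram(lower, bins=128)
        mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        out = v - mode
        prov = {"method": "offset", "offset_nm": float(mode)}
    res = hm.with_values(out)
    res.meta["background"] = prov
    return res


def normalize_height(hm: HeightMap) -> NormalizedImage:
    """Min-max rescale to [0, 1], recording the nm range used."""
    vmin = float(hm.values.min())
    vmax = float(hm.values.max())
    if vmax == vmin:
        raise ValueError("constant image: min-max normalization undefined")
    return NormalizedImage((hm.values - vmin) / (vmax - vmin), vmin, vmax)


def _otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold with a mid-plateau tie-break.

    On well-separated bimodal data the between-class variance is flat
    across the empty gap between the modes; the maximizing threshold is
    then ambiguous, and this implementation returns the midpoint of the
    maximizing plateau (rather than its lower edge), which centers the
    threshold in the gap.
    """
    hist, edges = np.histogram(values.ravel(), bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    p = w / w.sum()
    omega0 = np.cumsum(p)[:-1]
    omega1 = 1.0 - omega0
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma_b = (mu_t * omega0 - mu[:-1]) ** 2 / (omega0 * omega1)
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    best = sigma_b.max()
    plateau = np.nonzero(sigma_b >= best - 1e-12 * max(best, 1.0))[0]
    # threshold between bin i and i+1 -> use the shared edge
    lo, hi = edges[plateau[0] + 1], edges[plateau[-1] + 1]
    return float(0.5 * (lo + hi))


def binarize(hm: HeightMap, method: str = "otsu",
             threshold_nm: float | None = None) -> BinaryMask:
    """Threshold the height map; mask is True where height >= threshold.

    ``otsu`` picks the threshold maximizing between-class variance on the
    height histogram, centered within the inter-mode gap when the
    maximum is a plateau (errors on a constant image); ``fixed``
    requires ``threshold_nm``.  Provenance records the method and
    realized value.
    """
    if method == "fixed":
        if threshold_nm is None:
            raise ValueError("fixed binarization requires threshold_nm")
        thr = float(threshold_nm)
    elif method == "otsu":
        if np.ptp(hm.values) == 0:
            raise ValueError("Otsu threshold undefined on a constant image")
        thr = _otsu_threshold(hm.values)
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    mask = hm.values >= thr
    return BinaryMask(mask, pixel_size_nm=hm.pixel_size_nm,
                      provenance={"method": method, "threshold_nm": thr})
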
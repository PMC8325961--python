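"""Ground-truthed phantom generators.

Two families of phantoms drive the test surface of the whole pipeline:

* **Molecule height maps** — elongated molecules rendered on a flat mica
  background: the strand-like portion is a ridge of Gaussian cross-section
  (FWHM = the apparent stripe width, a stand-in for tip-convolved EC
  repeats), optional knot-like bumps at scripted arclengths, an optional
  large membrane-proximal globule, and i.i.d. Gaussian scan noise.
  Bumps combine with the ridge by pixelwise maximum so scripted peak
  heights stay directly interpretable as the rendered maxima.

* **Bead fields** — brightfield-like images of dark microbeads on a light
  background, with aggregates built as connected clusters of overlapping
  bead disks whose footprint areas are controlled, plus background
  singleton beads and shot noise.

Every generator takes an explicit seed and is bit-deterministic for a
given (spec, seed).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .config import (
    DEFAULT_FRAME_SHAPE,
    DEFAULT_PIXEL_SIZE_NM,
    BEAD_DIAMETER_UM,
    BEAD_PIXEL_SIZE_UM,
    STRAIGHTNESS_THRESHOLD_DEG,
)
from .imaging import HeightMap, write_image

__all__ = [
    "MoleculeSpec",
    "MoleculeGroundTruth",
    "ClassPhantomLabel",
    "BeadFieldSpec",
    "bent_backbone",
    "make_molecule_phantom",
    "make_class_phantom",
    "make_folding_sequence",
    "make_bead_field",
    "write_phantom",
    "write_bead_field",
]

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # sigma -> full width at half maximum


@dataclass(frozen=True)
class MoleculeSpec:
    """Geometry and noise of one phantom molecule.

    Positions are physical (x, y) in nm; ``knots`` and ``globule`` are
    (arclength_nm, peak_height_nm, radius_nm) placed on the backbone
    (radius is the Gaussian sigma of the bump).  ``bend_sites`` records
    scripted (arclength_nm, signed bend angle in degrees) for ground
    truth; the backbone points themselves carry the realized geometry.
    """

    backbone_points: tuple[tuple[float, float], ...]
    stripe_width_nm: float = 7.5
    strand_height_nm: float = 3.0
    knots: tuple[tuple[float, float, float], ...] = ()
    globule: tuple[float, float, float] | None = None
    bend_sites: tuple[tuple[float, float], ...] = ()
    noise_sd_nm: float = 0.0
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    frame_shape_px: tuple[int, int] = DEFAULT_FRAME_SHAPE
    seed: int = 0

    def validate(self) -> None:
        if len(self.backbone_points) < 1:
            raise ValueError("backbone needs at least one point")
        if not self.stripe_width_nm > 0:
            raise ValueError("stripe_width_nm must be > 0")
        if not self.strand_height_nm >= 0:
            raise ValueError("strand_height_nm must be >= 0")
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.noise_sd_nm < 0:
            raise ValueError("noise_sd_nm must be >= 0")
        total = self.contour_length_nm
        tol = 1e-6 * max(1.0, total)  # float slack for endpoint features
        for pos, ang in self.bend_sites:
            if not -180.0 < ang < 180.0:
                raise ValueError(f"bend angle {ang} deg outside (-180, 180)")
            if not -tol <= pos <= total + tol:
                raise ValueError(f"bend site at {pos} nm off the backbone")
        for what, items in (("knot", self.knots),
                            ("globule", (self.globule,) if self.globule else ())):
            for pos, peak, radius in items:
                if not (peak > 0 and radius > 0):
                    raise ValueError(f"{what} peak/radius must be > 0")
                if not -tol <= pos <= total + tol:
                    raise ValueError(f"{what} at arclength {pos} nm is off "
                                     f"the backbone (contour {total:.1f} nm)")
        nr, nc = self.frame_shape_px
        xmax = (nc - 1) * self.pixel_size_nm
        ymax = (nr - 1) * self.pixel_size_nm
        for p in self.backbone_points:
            x, y = p
            if not (0.0 <= x <= xmax and 0.0 <= y <= ymax):
                raise ValueError(
                    f"backbone point ({x:.1f}, {y:.1f}) nm exits the "
                    f"{xmax:.1f} x {ymax:.1f} nm frame"
                )

    @property
    def contour_length_nm(self) -> float:
        pts = np.asarray(self.backbone_points, dtype=float)
        if len(pts) < 2:
            return 0.0
        return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))


@dataclass
class MoleculeGroundTruth:
    """What the generator knows about a rendered phantom."""

    spec: MoleculeSpec
    end_to_end_nm: float           # max pairwise distance between backbone points
    footprint_length_nm: float     # max chord of the suprathreshold footprint
    footprint_area_nm2: float
    footprint_mask: np.ndarray
    footprint_threshold_nm: float
    knot_xy_nm: list[tuple[float, float]]
    globule_xy_nm: tuple[float, float] | None
    bend_angles_deg: list[float]
    noiseless: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class ClassPhantomLabel:
    """Ground truth for a morphology-class phantom."""

    class_id: int
    terminal_knot_count: int
    linker_bend_deg: float

    def __post_init__(self) -> None:
        if self.class_id not in (1, 2, 3):
            raise ValueError(f"class_id must be 1, 2 or 3, got {self.class_id}")


def bent_backbone(length_nm: float,
                  bend_sites: tuple[tuple[float, float], ...] = (),
                  start_xy_nm: tuple[float, float] = (0.0, 0.0),
                  direction_deg: float = 0.0) -> tuple[tuple[float, float], ...]:
    """Polyline of total contour length ``length_nm`` starting at
    ``start_xy_nm`` heading ``direction_deg`` (ccw from +x), turning by the
    signed angle at each scripted arclength."""
    sites = sorted(bend_sites, key=lambda s: s[0])
    pts = [tuple(map(float, start_xy_nm))]
    heading = np.deg2rad(direction_deg)
    s_prev = 0.0
    for s_pos, ang in sites:
        if not 0.0 <= s_pos <= length_nm:
            raise ValueError(f"bend site {s_pos} nm outside [0, {length_nm}]")
        seg = s_pos - s_prev
        x, y = pts[-1]
        pts.append((x + seg * np.cos(heading), y + seg * np.sin(heading)))
        heading += np.deg2rad(ang)
        s_prev = s_pos
    x, y = pts[-1]
    seg = length_nm - s_prev
    pts.append((x + seg * np.cos(heading), y + seg * np.sin(heading)))
    # drop zero-length duplicates (bend at an endpoint)
    out = [pts[0]]
    for p in pts[1:]:
        if np.hypot(p[0] - out[-1][0], p[1] - out[-1][1]) > 1e-9:
            out.append(p)
    return tuple(out)


def _polyline_arclength_point(pts: np.ndarray, s: float) -> np.ndarray:
    """Point at arclength ``s`` along the polyline (clamped to the ends)."""
    if len(pts) == 1:
        return pts[0]
    seg = np.hypot(*np.diff(pts, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = float(np.clip(s, 0.0, cum[-1]))
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(i, len(seg) - 1)
    t = 0.0 if seg[i] == 0 else (s - cum[i]) / seg[i]
    return pts[i] + t * (pts[i + 1] - pts[i])


def _dist_to_polyline(px_x: np.ndarray, px_y: np.ndarray,
                      pts: np.ndarray) -> np.ndarray:
    """Distance from every pixel position to the polyline (nm)."""
    if len(pts) == 1:
        return np.hypot(px_x - pts[0, 0], px_y - pts[0, 1])
    d = np.full(px_x.shape, np.inf)
    for a, b in zip(pts[:-1], pts[1:]):
        ab = b - a
        denom = float(ab @ ab)
        t = ((px_x - a[0]) * ab[0] + (px_y - a[1]) * ab[1]) / denom
        t = np.clip(t, 0.0, 1.0)
        d = np.minimum(d, np.hypot(px_x - (a[0] + t * ab[0]),
                                   px_y - (a[1] + t * ab[1])))
    return d


def _max_chord(points_xy: np.ndarray) -> float:
    """Maximum pairwise distance via convex hull (falls back to all pairs)."""
    if len(points_xy) < 2:
        return 0.0
    try:
        from scipy.spatial import ConvexHull
        hull = points_xy[ConvexHull(points_xy).vertices]
    except Exception:  # collinear / tiny sets
        hull = points_xy
    diff = hull[:, None, :] - hull[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).max())


def make_molecule_phantom(spec: MoleculeSpec) -> tuple[HeightMap, MoleculeGroundTruth]:
    """Render one molecule phantom and its ground truth.

    The strand is a ridge of Gaussian cross-section with FWHM equal to
    ``stripe_width_nm`` and crest height ``strand_height_nm``; knots and
    the globule are radially symmetric Gaussian bumps combined with the
    ridge by pixelwise maximum.  Ground truth records the backbone
    end-to-end distance, the suprathreshold (half-crest) footprint with
    its area and maximum chord, and the scripted feature positions.
    """
    spec.validate()
    nr, nc = spec.frame_shape_px
    px = spec.pixel_size_nm
    cols, rows = np.meshgrid(np.arange(nc), np.arange(nr))
    X = cols * px
    Y = rows * px
    pts = np.asarray(spec.backbone_points, dtype=float)

    d = _dist_to_polyline(X, Y, pts)
    sigma_r = spec.stripe_width_nm / _FWHM
    ridge = spec.strand_height_nm * np.exp(-d ** 2 / (2.0 * sigma_r ** 2))
    height = ridge

    knot_xy: list[tuple[float, float]] = []
    globule_xy: tuple[float, float] | None = None
    bumps = list(spec.knots)
    if spec.globule is not None:
        bumps.append(tuple(spec.globule))
    for i, (s_pos, peak, radius) in enumerate(bumps):
        cx, cy = _polyline_arclength_point(pts, s_pos)
        r2 = (X - cx) ** 2 + (Y - cy) ** 2
        bump = peak * np.exp(-r2 / (2.0 * radius ** 2))
        height = np.maximum(height, bump)
        if i < len(spec.knots):
            knot_xy.append((float(cx), float(cy)))
        else:
            globule_xy = (float(cx), float(cy))

    noiseless = height.copy()
    if spec.noise_sd_nm > 0:
        rng = np.random.default_rng(spec.seed)
        height = height + rng.normal(0.0, spec.noise_sd_nm, size=height.shape)

    # footprint at half the crest height (the width-defining level); for a
    # strand-free phantom fall back to half the tallest bump
    ref = spec.strand_height_nm if spec.strand_height_nm > 0 else float(noiseless.max())
    thr = 0.5 * ref
    footprint = noiseless >= thr
    area_nm2 = float(footprint.sum()) * px * px
    fp_xy = np.column_stack([X[footprint], Y[footprint]])
    gt = MoleculeGroundTruth(
        spec=spec,
        end_to_end_nm=_max_chord(pts),
        footprint_length_nm=_max_chord(fp_xy),
        footprint_area_nm2=area_nm2,
        footprint_mask=footprint,
        footprint_threshold_nm=thr,
        knot_xy_nm=knot_xy,
        globule_xy_nm=globule_xy,
        bend_angles_deg=[float(a) for _, a in spec.bend_sites],
        noiseless=noiseless,
    )
    return HeightMap(height, pixel_size_nm=px), gt


def _centered_backbone(length_nm, bends, direction_deg, spec_kwargs):
    """Build a bent backbone and translate it to the frame center."""
    pts = np.asarray(bent_backbone(length_nm, bends, (0.0, 0.0), direction_deg))
    nr, nc = spec_kwargs.get("frame_shape_px", DEFAULT_FRAME_SHAPE)
    px = spec_kwargs.get("pixel_size_nm", DEFAULT_PIXEL_SIZE_NM)
    center = np.array([(nc - 1) * px / 2.0, (nr - 1) * px / 2.0])
    mid = 0.5 * (pts.min(axis=0) + pts.max(axis=0))
    pts = pts - mid + center
    return tuple(map(tuple, pts))


def make_class_phantom(class_id: int, seed: int,
                       noise_sd_nm: float = 0.0,
                       straightness_deg: float = STRAIGHTNESS_THRESHOLD_DEG,
                       **spec_kwargs) -> tuple[HeightMap, ClassPhantomLabel]:
    """Phantom of one morphology class with its ground-truth label.

    Class 1: two terminal knots joined by a straight rod-like linker
    (scripted bend well below the straightness threshold).  Class 2: two
    terminal knots joined by a bent/kinked linker (bend well above it).
    Class 3: other morphologies — a single-knot molecule, a compact
    ball-like molecule, or a multiply folded strand — drawn at random.
    """
    if class_id not in (1, 2, 3):
        raise ValueError(f"class_id must be 1, 2 or 3, got {class_id}")
    rng = np.random.default_rng(seed)
    direction = float(rng.uniform(0.0, 180.0))
    length = float(rng.uniform(60.0, 90.0))
    # tip convolution broadens every feature to at least the strand's
    # apparent width, so knot bumps are never narrower than the strand
    # ridge (sigma ~3.2 nm at the default 7.5 nm FWHM)
    knot_peak = lambda: float(rng.uniform(4.2, 4.8))
    knot_radius = lambda: float(rng.uniform(3.2, 4.2))

    if class_id in (1, 2):
        if class_id == 1:
            bend = float(rng.uniform(0.0, 0.5 * straightness_deg))
        else:
            bend = float(rng.uniform(1.5 * straightness_deg, 120.0))
        bend *= -1.0 if rng.random() < 0.5 else 1.0
        bends = ((length / 2.0, bend),)
        pts = _centered_backbone(length, bends, direction, spec_kwargs)
        knots = ((0.0, knot_peak(), knot_radius()),
                 (length, knot_peak(), knot_radius()))
        spec = MoleculeSpec(backbone_points=pts, knots=knots, bend_sites=bends,
                            noise_sd_nm=noise_sd_nm, seed=seed, **spec_kwargs)
        label = ClassPhantomLabel(class_id, 2, abs(bend))
    else:
        kind = rng.choice(["single_knot", "ball", "folded"])
        if kind == "single_knot":
            bend = float(rng.uniform(0.0, 20.0)) * (-1.0 if rng.random() < 0.5 else 1.0)
            bends = ((length / 2.0, bend),)
            pts = _centered_backbone(length, bends, direction, spec_kwargs)
            spec = MoleculeSpec(backbone_points=pts,
                                knots=((0.0, knot_peak(), knot_radius()),),
                                bend_sites=bends, noise_sd_nm=noise_sd_nm,
                                seed=seed, **spec_kwargs)
            label = ClassPhantomLabel(3, 1, abs(bend))
        elif kind == "ball":
            length = float(rng.uniform(8.0, 14.0))
            pts = _centered_backbone(length, (), direction, spec_kwargs)
            spec = MoleculeSpec(backbone_points=pts,
                                globule=(length / 2.0, float(rng.uniform(5.2, 6.0)),
                                         float(rng.uniform(4.0, 5.5))),
                                noise_sd_nm=noise_sd_nm, seed=seed, **spec_kwargs)
            label = ClassPhantomLabel(3, 0, 0.0)
        else:  # multiply folded strand, no knots
            n_bends = int(rng.integers(2, 4))
            positions = np.sort(rng.uniform(0.25, 0.75, size=n_bends)) * length
            angles = rng.uniform(95.0, 150.0, size=n_bends)
            signs = rng.choice([-1.0, 1.0], size=n_bends)
            bends = tuple((float(p), float(a * s))
                          for p, a, s in zip(positions, angles, signs))
            pts = _centered_backbone(length, bends, direction, spec_kwargs)
            spec = MoleculeSpec(backbone_points=pts, bend_sites=bends,
                                noise_sd_nm=noise_sd_nm, seed=seed, **spec_kwargs)
            label = ClassPhantomLabel(3, 0, float(np.max(np.abs([a for _, a in bends]))))

    hm, _ = make_molecule_phantom(spec)
    return hm, label


def make_folding_sequence(n_frames: int, seed: int,
                          bend_angles_deg: np.ndarray | None = None,
                          noise_sd_nm: float = 0.15,
                          **spec_kwargs) -> tuple[list[HeightMap], list[MoleculeGroundTruth]]:
    """Image sequence of one molecule folding and unfolding.

    Each frame is rendered independently with a scripted mid-backbone bend
    angle (default: a fold/unfold sweep 0 -> 140 -> 0 degrees).  Returns
    the frames and per-frame ground truth, whose ``footprint_length_nm``
    is the generator's oracle for the measured length.
    """
    if bend_angles_deg is None:
        half = n_frames // 2 + 1
        up = np.linspace(0.0, 140.0, half)
        bend_angles_deg = np.concatenate([up, up[-2::-1]])[:n_frames]
    length = 80.0
    frames, truths = [], []
    for i in range(n_frames):
        bend = float(bend_angles_deg[i])
        bends = ((length / 2.0, bend),) if abs(bend) > 1e-9 else ()
        pts = _centered_backbone(length, bends, 0.0, spec_kwargs)
        spec = MoleculeSpec(backbone_points=pts, bend_sites=bends,
                            noise_sd_nm=noise_sd_nm, seed=seed + i, **spec_kwargs)
        hm, gt = make_molecule_phantom(spec)
        hm.frame_id = i
        frames.append(hm)
        truths.append(gt)
    return frames, truths


@dataclass(frozen=True)
class BeadFieldSpec:
    """A brightfield bead-assay field: aggregates of scripted footprint
    area (µm²) at scripted centers (px), plus background singletons."""

    image_size_px: tuple[int, int] = (512, 512)  # (width, height)
    pixel_size_um: float = BEAD_PIXEL_SIZE_UM
    bead_diameter_um: float = BEAD_DIAMETER_UM
    aggregates: tuple[tuple[tuple[float, float], float], ...] = ()
    n_singletons: int = 0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (self.pixel_size_um > 0 and self.bead_diameter_um > 0):
            raise ValueError("pixel_size_um and bead_diameter_um must be > 0")
        w, h = self.image_size_px
        for (cx, cy), area in self.aggregates:
            if not area > 0:
                raise ValueError("aggregate target areas must be > 0")
            # radius the aggregate could reach if grown as a compact disk
            r_px = 2.0 * np.sqrt(area / np.pi) / self.pixel_size_um
            if not (r_px <= cx <= w - 1 - r_px and r_px <= cy <= h - 1 - r_px):
                raise ValueError(f"aggregate at ({cx}, {cy}) px may exit the frame")

    @property
    def bead_area_um2(self) -> float:
        return float(np.pi * (self.bead_diameter_um / 2.0) ** 2)


def _disk_mask(mask: np.ndarray, cx: float, cy: float, r_px: float) -> None:
    h, w = mask.shape
    x0, x1 = max(0, int(cx - r_px - 1)), min(w, int(cx + r_px + 2))
    y0, y1 = max(0, int(cy - r_px - 1)), min(h, int(cy + r_px + 2))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask[y0:y1, x0:x1] |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r_px ** 2


def make_bead_field(spec: BeadFieldSpec) -> tuple[np.ndarray, list[float]]:
    """Render a bead field and return (8-bit-range float image, realized
    per-aggregate areas in µm²).

    Each aggregate is grown as a cluster of overlapping bead disks until
    its footprint is within half a bead area of the target (guaranteeing
    a realized error below one bead area).  Aggregates may not touch each
    other or background singletons — ground truth would be ambiguous.
    """
    spec.validate()
    w, h = spec.image_size_px
    rng = np.random.default_rng(spec.seed)
    px_area_um2 = spec.pixel_size_um ** 2
    bead_r_px = (spec.bead_diameter_um / 2.0) / spec.pixel_size_um
    bead_area = spec.bead_area_um2

    # exclusion bookkeeping: (cx, cy, reach) bounding circles
    occupied: list[tuple[float, float, float]] = []
    full = np.zeros((h, w), dtype=bool)
    realized: list[float] = []
    for (cx, cy), target in spec.aggregates:
        reach = 2.0 * np.sqrt(target / np.pi) / spec.pixel_size_um + 2 * bead_r_px
        for ox, oy, orad in occupied:
            if np.hypot(cx - ox, cy - oy) < reach + orad:
                raise ValueError(
                    f"aggregate at ({cx}, {cy}) px overlaps another object"
                )
        occupied.append((cx, cy, reach))
        agg = np.zeros((h, w), dtype=bool)
        # candidate bead centers: jittered hex lattice over the reach disk,
        # consumed nearest-first so the cluster grows compactly until the
        # footprint is within half a bead area of the target
        spacing = 1.4 * bead_r_px
        row_h = spacing * np.sqrt(3.0) / 2.0
        cand = []
        for i, dy in enumerate(np.arange(-reach, reach + row_h, row_h)):
            offs = spacing / 2.0 if i % 2 else 0.0
            for dx in np.arange(-reach, reach + spacing, spacing) + offs:
                if np.hypot(dx, dy) <= reach - bead_r_px:
                    cand.append((dx, dy))
        cand = np.asarray(cand) + rng.normal(0.0, 0.25 * bead_r_px,
                                             size=(len(cand), 2))
        order = np.argsort(np.hypot(cand[:, 0], cand[:, 1])
                           + rng.uniform(0.0, 0.5 * bead_r_px, len(cand)))
        done = False
        for idx in order:
            if agg.sum() * px_area_um2 >= target - 0.5 * bead_area:
                done = True
                break
            _disk_mask(agg, cx + cand[idx, 0], cy + cand[idx, 1], bead_r_px)
        if not done and agg.sum() * px_area_um2 < target - 0.5 * bead_area:
            raise RuntimeError("aggregate growth did not converge")
        realized.append(float(agg.sum()) * px_area_um2)
        full |= agg

    for _ in range(spec.n_singletons):
        for _attempt in range(200):
            sx = rng.uniform(2 * bead_r_px, w - 1 - 2 * bead_r_px)
            sy = rng.uniform(2 * bead_r_px, h - 1 - 2 * bead_r_px)
            clear = all(np.hypot(sx - ox, sy - oy) > orad + 3 * bead_r_px
                        for ox, oy, orad in occupied)
            if clear:
                break
        else:
            break
        occupied.append((sx, sy, 2 * bead_r_px))
        _disk_mask(full, sx, sy, bead_r_px)

    image = np.full((h, w), 200.0)
    image[full] = 60.0
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    return np.clip(image, 0.0, 255.0), realized


def write_phantom(hm: HeightMap, gt: MoleculeGroundTruth, stem: str | Path) -> None:
    """Write a phantom as float TIFF plus a JSON sidecar (spec + truth)."""
    stem = Path(stem)
    write_image(hm, stem.with_suffix(".tiff"))
    payload = {
        "spec": asdict(gt.spec),
        "end_to_end_nm": gt.end_to_end_nm,
        "footprint_length_nm": gt.footprint_length_nm,
        "footprint_area_nm2": gt.footprint_area_nm2,
        "footprint_threshold_nm": gt.footprint_threshold_nm,
        "knot_xy_nm": gt.knot_xy_nm,
        "globule_xy_nm": gt.globule_xy_nm,
        "bend_angles_deg": gt.bend_angles_deg,
    }
    stem.with_suffix(".json").write_text(json.dumps(payload, indent=2))


def write_bead_field(image: np.ndarray, areas: list[float], stem: str | Path) -> None:
    """Write a bead field as 8-bit PNG plus a CSV ground-truth table."""
    stem = Path(stem)
    iio.imwrite(stem.with_suffix(".png"), np.round(image).astype(np.uint8))
    lines = ["aggregate_id,area_um2"]
    lines += [f"{i},{a:.6f}" for i, a in enumerate(areas)]
    stem.with_suffix(".csv").write_text("\n".join(lines) + "\n")
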
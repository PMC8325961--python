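"""Object labeling, lengths, ellipses, profiles, volumes, tracking."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from afmstripes.imaging import BinaryMask, HeightMap, binarize
from afmstripes.morphometry import (
    MoleculeRecord,
    backbone_height_profile,
    fit_ellipse,
    label_objects,
    max_height,
    max_length,
    select_by_area,
    track_over_frames,
    volume_fraction,
)
from afmstripes.synthetic import (
    MoleculeSpec,
    make_folding_sequence,
    make_molecule_phantom,
)
from conftest import make_map

FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


def mask_of(arr, px=1.5):
    return BinaryMask(np.asarray(arr, bool), px,
                      {"method": "fixed", "threshold_nm": 0.5})


def record_of(pixels, px=1.5):
    pixels = np.asarray(pixels)
    return MoleculeRecord(0, pixels, px, len(pixels) * px * px)


def bfs_components(mask):
    """Naive 8-connected flood fill, independent of scipy labeling."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    sizes = []
    for r0, c0 in zip(*np.nonzero(mask)):
        if seen[r0, c0]:
            continue
        stack, size = [(r0, c0)], 0
        seen[r0, c0] = True
        while stack:
            r, c = stack.pop()
            size += 1
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]
                            and mask[rr, cc] and not seen[rr, cc]):
                        seen[rr, cc] = True
                        stack.append((rr, cc))
        sizes.append(size)
    return sizes


class TestLabel:
    def test_two_blobs_counted_with_areas(self):
        m = np.zeros((20, 20), bool)
        m[2:4, 2:7] = True   # 10 px
        m[10:12, 10:15] = True
        recs = label_objects(mask_of(m), min_area_px=5)
        assert len(recs) == 2
        for r in recs:
            assert r.area_nm2 == pytest.approx(10 * 1.5 ** 2)

    def test_small_blob_dropped(self):
        m = np.zeros((10, 10), bool)
        m[2:4, 2:4] = True  # 4 px
        assert label_objects(mask_of(m), min_area_px=5) == []

    def test_empty_mask_gives_empty_list(self):
        assert label_objects(mask_of(np.zeros((8, 8)))) == []

    def test_component_count_matches_bfs_oracle(self, rng):
        m = rng.random((64, 64)) < 0.3
        recs = label_objects(mask_of(m), min_area_px=1)
        oracle = bfs_components(m)
        assert len(recs) == len(oracle)
        assert sorted(r.area_px for r in recs) == sorted(oracle)


class TestSelectByArea:
    def test_adversarial_outlier_excluded(self):
        recs = [record_of([[0, i]]) for i in range(4)]
        for r, a in zip(recs, (1.0, 2.0, 3.0, 100.0)):
            r.area_nm2 = a
        select_by_area(recs)
        areas = np.array([1.0, 2.0, 3.0, 100.0])
        lo, hi = areas.mean() - areas.std(ddof=1), areas.mean() + areas.std(ddof=1)
        for r in recs:
            assert r.selected == (lo <= r.area_nm2 <= hi)
        assert [r.selected for r in recs] == [True, True, True, False]

    def test_equal_areas_all_selected(self):
        recs = [record_of([[0, i]]) for i in range(3)]
        select_by_area(recs)
        assert all(r.selected for r in recs)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError, match="2"):
            select_by_area([record_of([[0, 0]])])

    @given(st.lists(st.floats(min_value=0.1, max_value=1e4,
                               allow_nan=False), min_size=2, max_size=20),
           st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=50, deadline=None)
    def test_selection_invariant_under_uniform_rescale(self, areas, factor):
        def run(vals):
            recs = [record_of([[0, i]]) for i in range(len(vals))]
            for r, a in zip(recs, vals):
                r.area_nm2 = float(a)
            select_by_area(recs)
            return [r.selected for r in recs]
        assert run(areas) == run([a * factor for a in areas])

    def test_invariant_to_order_and_rescale(self, rng):
        areas = rng.uniform(10, 500, size=12)
        def run(vals):
            recs = [record_of([[0, i]]) for i in range(len(vals))]
            for r, a in zip(recs, vals):
                r.area_nm2 = float(a)
            select_by_area(recs)
            return [r.selected for r in recs]
        base = run(areas)
        perm = rng.permutation(len(areas))
        assert [run(areas[perm])[i] for i in np.argsort(perm)] == base
        assert run(areas * 7.3) == base


class TestMaxLength:
    def test_single_pixel_zero(self):
        assert max_length(record_of([[5, 5]])) == 0.0

    def test_collinear_run(self):
        pixels = [[7, c] for c in range(101)]
        assert max_length(record_of(pixels)) == pytest.approx(100 * 1.5)

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(5):
            m = np.zeros((40, 40), bool)
            rr = rng.integers(5, 35, 200)
            cc = rng.integers(5, 35, 200)
            m[rr, cc] = True
            pts = np.argwhere(m).astype(float)
            rec = record_of(np.argwhere(m))
            diff = pts[:, None] - pts[None, :]
            brute = np.sqrt((diff ** 2).sum(-1)).max() * 1.5
            assert max_length(rec) == pytest.approx(brute, abs=1e-9)


class TestFitEllipse:
    def test_digital_disk_is_isotropic(self):
        yy, xx = np.mgrid[:50, :50]
        m = (yy - 25.0) ** 2 + (xx - 25.0) ** 2 <= 20.0 ** 2
        a, b, _ = fit_ellipse(record_of(np.argwhere(m), px=1.0))
        assert a == pytest.approx(40.0, rel=0.02)
        assert b == pytest.approx(40.0, rel=0.02)

    def test_rectangle_matches_analytic_moments(self):
        # continuous w x h rectangle: second moment w^2/12 -> raw axis
        # 2w/sqrt(3), rescaled by sqrt(3/pi) for area match -> 2w/sqrt(pi)
        w, h = 40, 12
        m = np.zeros((30, 60), bool)
        m[9:9 + h, 10:10 + w] = True
        a, b, ang = fit_ellipse(record_of(np.argwhere(m), px=1.0))
        assert a == pytest.approx(2 * w / np.sqrt(np.pi), rel=1e-6)
        assert b == pytest.approx(2 * h / np.sqrt(np.pi), rel=1e-6)
        assert ang % 180.0 == pytest.approx(0.0, abs=1e-6)

    def test_rotated_ellipse_recovered(self):
        yy, xx = np.mgrid[:100, :100]
        t = np.deg2rad(25.0)
        # major axis along visual ccw 25 deg: direction (cos t, -sin t)
        # in (col, row) coordinates with the row axis pointing down
        u = (xx - 50) * np.cos(t) - (yy - 50) * np.sin(t)
        v = (xx - 50) * np.sin(t) + (yy - 50) * np.cos(t)
        m = (u / 30.0) ** 2 + (v / 8.0) ** 2 <= 1.0
        a, b, ang = fit_ellipse(record_of(np.argwhere(m), px=1.0))
        assert a == pytest.approx(60.0, rel=0.05)
        assert b == pytest.approx(16.0, rel=0.05)
        assert min(abs(ang - 25.0), abs(ang - 205.0)) < 3.0

    def test_area_consistency(self, rng):
        m = rng.random((40, 40)) < 0.5
        m = ndimage.binary_closing(m)
        rec = record_of(np.argwhere(m), px=1.0)
        a, b, _ = fit_ellipse(rec)
        assert np.pi * (a / 2) * (b / 2) == pytest.approx(rec.area_px, rel=0.005)

    def test_collinear_flagged_degenerate(self):
        rec = record_of([[5, c] for c in range(10)], px=1.0)
        a, b, _ = fit_ellipse(rec)
        assert rec.ellipse_degenerate
        assert b == pytest.approx(1.0)

    def test_too_few_pixels_rejected(self):
        with pytest.raises(ValueError):
            fit_ellipse(record_of([[0, 0], [0, 1]]))


class TestProfile:
    def _rod(self, bump=None):
        spec = MoleculeSpec(
            backbone_points=((60.0, 180.0), (240.0, 180.0)),
            globule=bump,
        )
        hm, gt = make_molecule_phantom(spec)
        mask = binarize(hm, "fixed", threshold_nm=1.5)
        rec = label_objects(mask, min_area_px=10)[0]
        return hm, rec

    def test_uniform_rod_flat_profile(self):
        hm, rec = self._rod()
        prof = backbone_height_profile(rec, hm)
        assert not prof.fallback_axis
        inner = (prof.arclength_nm > 10) & (prof.arclength_nm < prof.arclength_nm[-1] - 10)
        assert np.allclose(prof.heights_nm[inner], 3.0, atol=0.05)
        assert prof.local_maxima == []

    def test_midpoint_bump_found_once(self):
        hm, rec = self._rod(bump=(90.0, 6.0, 4.0))
        prof = backbone_height_profile(rec, hm)
        assert len(prof.local_maxima) == 1
        pos, height = prof.local_maxima[0]
        assert height == pytest.approx(6.0, abs=0.2)
        assert abs(pos - prof.arclength_nm[-1] / 2) <= 2 * 1.5  # within 2 px

    def test_endpoints_are_most_distant_tips(self):
        hm, rec = self._rod()
        prof = backbone_height_profile(rec, hm)
        tips = prof.path_rc[[0, -1]]
        span = np.hypot(*(tips[0] - tips[1])) * 1.5
        # the skeleton path spans nearly the whole rod
        assert span >= 0.8 * rec.length_nm

    def test_disk_falls_back_to_axis(self):
        yy, xx = np.mgrid[:40, :40]
        m = (yy - 20) ** 2 + (xx - 20) ** 2 <= 16
        hm = make_map(np.where(m, 3.0, 0.0))
        rec = label_objects(mask_of(m), min_area_px=1)[0]
        prof = backbone_height_profile(rec, hm)
        assert prof.fallback_axis


class TestMaxHeight:
    def test_globule_peak_recovered(self):
        spec = MoleculeSpec(backbone_points=((60.0, 180.0), (160.0, 180.0)),
                            globule=(60.0, 5.9, 5.0))
        hm, _ = make_molecule_phantom(spec)
        mask = binarize(hm, "fixed", threshold_nm=1.5)
        rec = label_objects(mask, min_area_px=10)[0]
        assert max_height(rec, hm) == pytest.approx(5.9, abs=0.1)

    def test_translation_equivariance(self, straight_phantom):
        hm, _ = straight_phantom
        mask = binarize(hm, "fixed", threshold_nm=1.5)
        rec = label_objects(mask, min_area_px=10)[0]
        h0 = max_height(rec, hm)
        h1 = max_height(rec, hm.with_values(hm.values + 1.0))
        assert h1 - h0 == pytest.approx(1.0, abs=1e-12)


class TestVolumeFraction:
    def test_identity_and_empty(self, straight_phantom):
        hm, gt = straight_phantom
        obj = gt.footprint_mask
        assert volume_fraction(hm, obj, obj) == 1.0
        assert volume_fraction(hm, np.zeros_like(obj), obj) == 0.0

    def test_complement_partition(self, straight_phantom):
        hm, gt = straight_phantom
        obj = gt.footprint_mask
        region = obj.copy()
        region[:, :70] = False
        f1 = volume_fraction(hm, region, obj)
        f2 = volume_fraction(hm, obj & ~region, obj)
        assert f1 + f2 == pytest.approx(1.0, abs=1e-12)

    def test_globule_equal_to_strand_gives_half(self):
        # peak 6.1997 nm, sigma 6 nm globule at the end of a 60 nm strand
        # splits the composite volume exactly in half across the
        # bump-dominant boundary (solved from the analytic forms)
        spec = MoleculeSpec(
            backbone_points=((120.0, 180.0), (180.0, 180.0)),
            stripe_width_nm=7.5, strand_height_nm=3.0,
            globule=(60.0, 6.199741246144849, 6.0),
        )
        hm, _ = make_molecule_phantom(spec)
        # independent reconstruction of ridge/bump dominance per pixel
        cols, rows = np.meshgrid(np.arange(240), np.arange(240))
        X, Y = cols * 1.5, rows * 1.5
        t = np.clip(X, 120.0, 180.0)
        d = np.hypot(X - t, Y - 180.0)
        s = 7.5 / FWHM
        ridge = 3.0 * np.exp(-d ** 2 / (2 * s ** 2))
        bump = 6.199741246144849 * np.exp(
            -((X - 180.0) ** 2 + (Y - 180.0) ** 2) / (2 * 36.0))
        obj = np.ones_like(ridge, dtype=bool)
        frac = volume_fraction(hm, bump >= ridge, obj)
        assert frac == pytest.approx(0.50, abs=0.02)

    def test_region_not_subset_rejected(self, straight_phantom):
        hm, gt = straight_phantom
        region = np.ones_like(gt.footprint_mask)
        with pytest.raises(ValueError, match="subset"):
            volume_fraction(hm, region, gt.footprint_mask)

    def test_zero_volume_rejected(self):
        hm = make_map(np.zeros((10, 10)))
        obj = np.ones((10, 10), bool)
        with pytest.raises(ValueError):
            volume_fraction(hm, obj, obj)


class TestRotationRobustness:
    def test_quarter_turn_changes_little(self, straight_phantom):
        hm, _ = straight_phantom
        rot = HeightMap(np.rot90(hm.values).copy(), hm.pixel_size_nm)
        out = []
        for m in (hm, rot):
            mask = binarize(m, "fixed", threshold_nm=1.5)
            rec = label_objects(mask, min_area_px=10)[0]
            fit_ellipse(rec)
            out.append((rec.length_nm, rec.ellipse_long_nm, rec.ellipse_short_nm))
        for a, b in zip(*out):
            assert abs(a - b) <= 0.01 * max(a, b)


class TestTracking:
    def test_identical_frames_single_constant_track(self, straight_phantom):
        hm, _ = straight_phantom
        frames = [HeightMap(hm.values.copy(), 1.5, frame_id=i) for i in range(5)]
        tracks = track_over_frames(frames, binarize_method="fixed",
                                   threshold_nm=1.5)
        assert len(tracks) == 1
        lengths = tracks[0].lengths_nm
        assert len(lengths) == 5
        assert all(l == lengths[0] for l in lengths)

    def test_folding_sequence_lengths_within_two_pixels(self):
        frames, truths = make_folding_sequence(8, seed=3)
        tracks = track_over_frames(frames, min_area_px=20)
        assert len(tracks) == 1
        for rec, gt in zip(tracks[0].records, truths):
            err = abs(rec.length_nm - gt.footprint_length_nm)
            assert err <= 2 * frames[0].pixel_size_nm

    def test_two_molecules_two_tracks_no_swaps(self):
        specs = [
            MoleculeSpec(backbone_points=((30.0, 60.0), (120.0, 60.0))),
            MoleculeSpec(backbone_points=((150.0, 270.0), (260.0, 270.0))),
        ]
        maps = [make_molecule_phantom(s)[0].values for s in specs]
        frames = [HeightMap(maps[0] + maps[1], 1.5, frame_id=i)
                  for i in range(4)]
        tracks = track_over_frames(frames, binarize_method="fixed",
                                   threshold_nm=1.5)
        assert len(tracks) == 2
        for tr in tracks:
            cents = np.array([r.centroid_rc for r in tr.records])
            assert np.ptp(cents, axis=0).max() < 1.0  # no identity swap

    def test_gap_closes_track(self, straight_phantom):
        hm, _ = straight_phantom
        blank = HeightMap(np.zeros_like(hm.values), 1.5)
        frames = [hm, blank, HeightMap(hm.values.copy(), 1.5)]
        tracks = track_over_frames(frames, binarize_method="fixed",
                                   threshold_nm=1.5)
        assert len(tracks) == 2  # reappearance gets a new id
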
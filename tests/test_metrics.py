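"""Feature-extraction tests: alignment invariance, region masking, and the
planted-signal responses of structure, color, and texture features."""

import numpy as np
import pytest
from skimage.draw import polygon as draw_polygon

from facetriad import metrics, synthgen
from facetriad.metrics import (
    extract_color,
    extract_structure,
    extract_texture,
    interior_region,
    normalize_landmarks,
    region_masks,
)
from facetriad.template import GROUP_SLICES, eye_centers, template_points


def _similarity(pts, angle_deg=0.0, scale=1.0, shift=(0.0, 0.0)):
    th = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return pts @ rot.T * scale + np.asarray(shift)


class TestNormalize:
    def test_invariants(self):
        norm = normalize_landmarks(template_points())
        left, right = eye_centers(norm.points)
        assert np.linalg.norm(right - left) == pytest.approx(1.0, abs=1e-9)
        assert np.linalg.norm((left + right) / 2) == pytest.approx(0.0, abs=1e-9)

    def test_idempotent(self):
        once = normalize_landmarks(template_points()).points
        twice = normalize_landmarks(once).points
        np.testing.assert_allclose(twice, once, atol=1e-9)

    @pytest.mark.parametrize("angle,scale,shift", [
        (30.0, 2.0, (5.0, -3.0)),
        (-120.0, 0.25, (100.0, 40.0)),
    ])
    def test_similarity_invariance(self, angle, scale, shift):
        base = normalize_landmarks(template_points()).points
        moved = normalize_landmarks(
            _similarity(template_points(), angle, scale, shift)
        ).points
        np.testing.assert_allclose(moved, base, atol=1e-6)

    def test_coincident_eyes_rejected(self):
        pts = template_points()
        pts[GROUP_SLICES["right_eye"]] = pts[GROUP_SLICES["left_eye"]]
        with pytest.raises(ValueError, match="coincide"):
            normalize_landmarks(pts)

    def test_brow_raise_normalized_offset(self):
        """Raising the brows by d px shifts normalized brow y by exactly
        d / interocular-distance (hand-applied similarity transform)."""
        d = 4.0
        pts = template_points()
        raised = pts.copy()
        for g in ("left_brow", "right_brow"):
            raised[GROUP_SLICES[g], 1] -= d
        base = normalize_landmarks(pts).points
        moved = normalize_landmarks(raised).points
        interocular = np.linalg.norm(np.subtract(*eye_centers(pts)))
        dy = base[GROUP_SLICES["left_brow"], 1] - moved[GROUP_SLICES["left_brow"], 1]
        np.testing.assert_allclose(dy, d / interocular, atol=1e-9)


class TestInteriorRegion:
    def test_collinear_landmarks_rejected(self):
        pts = np.column_stack([np.linspace(10, 100, 42), np.full(42, 50.0)])
        with pytest.raises(ValueError):
            interior_region(pts, (128, 128))

    def test_mask_smaller_than_image(self):
        mask, _ = interior_region(template_points(), (128, 128))
        assert 0 < mask.sum() < 128 * 128

    def test_mask_area_matches_polygon_oracle(self):
        """Mask area agrees with an independent rasterization of the hull
        polygon to within 1%."""
        from scipy.spatial import ConvexHull

        pts = template_points()
        mask, _ = interior_region(pts, (128, 128))
        hull = ConvexHull(pts)
        rr, cc = draw_polygon(pts[hull.vertices, 1], pts[hull.vertices, 0], (128, 128))
        oracle = np.zeros((128, 128), dtype=bool)
        oracle[rr, cc] = True
        assert mask.sum() == pytest.approx(oracle.sum(), rel=0.01)

    def test_regions_have_pixels(self):
        _, regions = interior_region(template_points(), (128, 128))
        masks = region_masks(regions, (128, 128))
        for name in ("brows", "eyes", "nose", "mouth", "cheeks"):
            assert masks[name].any(), name


class TestStructure:
    def test_similarity_invariant_features(self):
        a = extract_structure(normalize_landmarks(template_points()))
        b = extract_structure(
            normalize_landmarks(_similarity(template_points(), 45.0, 3.0, (7, 9)))
        )
        np.testing.assert_allclose(a.values, b.values, atol=1e-6)
        assert a.feature_names == b.feature_names

    def test_brow_raise_increases_gap_feature(self):
        d = 3.0
        pts = template_points()
        raised = pts.copy()
        for g in ("left_brow", "right_brow"):
            raised[GROUP_SLICES[g], 1] -= d
        interocular = np.linalg.norm(np.subtract(*eye_centers(pts)))
        f0 = extract_structure(normalize_landmarks(pts))
        f1 = extract_structure(normalize_landmarks(raised))
        i = f0.feature_names.index("brow_eye_gap_left")
        assert f1.values[i] - f0.values[i] == pytest.approx(d / interocular, abs=1e-6)

    def test_eye_mouth_distance_direction(self):
        """Shortening the eye-mouth distance lowers the feature value."""
        pts = template_points()
        shorter = pts.copy()
        shorter[GROUP_SLICES["mouth"], 1] -= 6.0
        f0 = extract_structure(normalize_landmarks(pts))
        f1 = extract_structure(normalize_landmarks(shorter))
        i = f0.feature_names.index("eye_mouth_distance")
        assert f1.values[i] < f0.values[i]


@pytest.fixture(scope="module")
def regions():
    _, regions = interior_region(template_points(), (128, 128))
    return regions


@pytest.fixture(scope="module")
def mask():
    mask, _ = interior_region(template_points(), (128, 128))
    return mask


class TestColor:
    def test_uniform_gray(self, regions):
        img = np.full((128, 128, 3), 0.5)
        fv = extract_color(img, regions)
        vals = dict(zip(fv.feature_names, fv.values))
        assert vals["eye_cheek_contrast"] == pytest.approx(0.0, abs=1e-12)
        assert vals["mouth_cheek_contrast"] == pytest.approx(0.0, abs=1e-12)
        region_means = [vals[f"{r}_labL_mean"] for r in ("brows", "eyes", "cheeks")]
        assert np.ptp(region_means) < 1e-12
        assert all(abs(vals[k]) < 1e-9 for k in vals if k.endswith("_sd"))

    def test_cheeks_painted_red(self, regions):
        img = np.full((128, 128, 3), 0.5)
        cheeks = region_masks(regions, (128, 128))["cheeks"]
        img[cheeks] = (1.0, 0.0, 0.0)
        fv = extract_color(img, regions)
        vals = dict(zip(fv.feature_names, fv.values))
        assert vals["cheeks_r_mean"] == pytest.approx(1.0)
        assert vals["eyes_r_mean"] == pytest.approx(0.5)
        assert vals["mouth_g_mean"] == pytest.approx(0.5)

    def test_eye_darkening_contrast(self, regions):
        """Darkening the eye region by 0.2 (all channels) raises the
        eye-cheek luminance contrast by ~0.2; oracle = the painted pixels."""
        img = np.full((128, 128, 3), 0.6)
        masks = region_masks(regions, (128, 128))
        img[masks["eyes"]] -= 0.2
        fv = extract_color(img, regions)
        vals = dict(zip(fv.feature_names, fv.values))
        assert vals["eye_cheek_contrast"] == pytest.approx(0.2, abs=0.02)

    def test_empty_region_rejected(self, regions):
        img = np.full((128, 128, 3), 0.5)
        bad = dict(regions)
        # polygon entirely outside the canvas rasterizes to zero pixels
        bad["mouth"] = np.array([[-10.0, -10.0], [-5.0, -10.0], [-10.0, -5.0]])
        with pytest.raises(ValueError, match="mouth"):
            extract_color(img, bad)


class TestTexture:
    def test_constant_image_zero_energy(self, mask):
        fv = extract_texture(np.full((128, 128, 3), 0.37), mask)
        np.testing.assert_allclose(fv.values, 0.0, atol=1e-12)

    def test_noise_increases_every_energy(self, mask, rng):
        clean = np.full((128, 128, 3), 0.5)
        noisy = np.clip(clean + rng.normal(0, 0.05, clean.shape), 0, 1)
        f0 = extract_texture(clean, mask)
        f1 = extract_texture(noisy, mask)
        assert np.all(f1.values > f0.values)

    def test_grating_peaks_at_matching_filter(self, mask):
        """A sinusoidal grating at a bank wavelength maximizes the
        mean-absolute energy of the matching orientation x scale filter."""
        yy = np.arange(128)[:, None] * np.ones((1, 128))
        img = (0.5 + 0.4 * np.sin(2 * np.pi * yy / 8.0))[..., None] * np.ones(3)
        fv = extract_texture(img, mask)
        absmean = {
            n: v for n, v in zip(fv.feature_names, fv.values) if n.endswith("absmean")
        }
        best = max(absmean, key=absmean.get)
        assert "wav8" in best

    def test_small_mask_rejected(self):
        tiny = np.zeros((128, 128), dtype=bool)
        tiny[60:64, 60:64] = True
        with pytest.raises(ValueError, match="filter support"):
            extract_texture(np.zeros((128, 128, 3)), tiny)


class TestBatchInvariants:
    def test_fixed_length_and_names_across_faces(self, small_cohort):
        records, _, _ = small_cohort
        for metric in metrics.METRICS:
            table = metrics.feature_table(records[:4], metric)
            assert table.notna().all().all()
            assert len(set(map(tuple, [table.columns]))) == 1

    def test_color_invariant_to_whole_face_translation(self):
        """Translating face + landmarks together leaves color features
        unchanged (regions move with the landmarks)."""
        params = synthgen.FaceGenParams(seed=6, idiosyncrasy_sd=0.0, pixel_noise_sd=0.0)
        rec = synthgen.make_face(params, "neutral", "female", "f0", 0, None)
        shift = np.array([5.0, -4.0])
        rolled = np.roll(rec.image, (int(shift[1]), int(shift[0])), axis=(0, 1))
        moved = rec.landmarks + shift
        _, reg0 = interior_region(rec.landmarks, rec.image.shape[:2])
        _, reg1 = interior_region(moved, rolled.shape[:2])
        f0 = extract_color(rec.image, reg0)
        f1 = extract_color(rolled, reg1)
        np.testing.assert_allclose(f0.values, f1.values, atol=0.01)
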
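"""The triad metrics: structure, color, and texture features from the face
interior.

* **structure** — similarity-normalised landmark coordinates (interocular
  distance 1, eye midpoint at the origin, eye line horizontal) concatenated
  with a fixed set of inter-landmark distances (brow-eye gaps, mouth width
  and curvature, eye-mouth distance, nose length).
* **color** — per-region channel statistics: RGB channel means, CIELAB
  mean/SD, plus eye-region and mouth-region versus cheek luminance-contrast
  features.  Contrast uses linear Rec.709 luminance of the raw [0,1] RGB so
  that an additive channel shift moves the feature by exactly that amount.
* **texture** — mean absolute response and response SD of a Gabor filter
  bank (4 orientations x 3 wavelengths) over the masked face interior,
  computed on mean-centred luminance so a constant image scores zero.

Feature vectors carry aligned names and have a fixed length per metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal import fftconvolve
from skimage.color import rgb2lab
from skimage.draw import polygon as draw_polygon
from skimage.filters import gabor_kernel

from facetriad.template import (
    GROUP_SLICES,
    N_LANDMARKS,
    MOUTH_BOTTOM_CENTER,
    MOUTH_LEFT_CORNER,
    MOUTH_RIGHT_CORNER,
    MOUTH_TOP_CENTER,
    check_template,
    eye_centers,
    group_points,
)

METRICS = ("structure", "color", "texture")

GABOR_ORIENTATIONS_DEG = (0.0, 45.0, 90.0, 135.0)
GABOR_WAVELENGTHS_PX = (4.0, 8.0, 16.0)

_LUMA = np.array([0.2126, 0.7152, 0.0722])


@dataclass
class FeatureVector:
    """A fixed-length named feature vector for one metric."""

    metric: str
    values: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if len(self.values) != len(self.feature_names):
            raise ValueError("values and feature_names must align")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")


@dataclass
class NormalizedLandmarks:
    """Landmarks after similarity alignment (interocular distance = 1)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        left, right = eye_centers(self.points)
        if abs(np.linalg.norm(right - left) - 1.0) > 1e-6:
            raise ValueError("normalized landmarks must have interocular distance 1")


def normalize_landmarks(landmarks: np.ndarray) -> NormalizedLandmarks:
    """Similarity-align a landmark set.

    Translates the eye midpoint to the origin, rotates the eye line
    horizontal (right eye toward +x), and scales the interocular distance
    to 1.  The output is invariant (to ~1e-6) under translation, rotation,
    and uniform scaling of the input.
    """
    pts = check_template(landmarks)
    left, right = eye_centers(pts)
    delta = right - left
    dist = np.linalg.norm(delta)
    if dist < 1e-9:
        raise ValueError("degenerate landmarks: eye centers coincide")
    mid = (left + right) / 2
    c, s = delta / dist
    # rotate by -angle(eye line); y is downward, rotation matrix unchanged
    rot = np.array([[c, s], [-s, c]])
    out = (pts - mid) @ rot.T / dist
    return NormalizedLandmarks(points=out)


# ---------------------------------------------------------------------------
# interior region masking
# ---------------------------------------------------------------------------

def _hull(pts: np.ndarray) -> np.ndarray:
    from scipy.spatial import ConvexHull, QhullError

    try:
        hull = ConvexHull(pts)
    except QhullError as err:
        raise ValueError("degenerate landmark set: empty convex hull") from err
    return pts[hull.vertices]


def _rasterize(poly: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape)
    mask[rr, cc] = True
    return mask


def _expand(poly: np.ndarray, pad: float) -> np.ndarray:
    c = poly.mean(axis=0)
    d = poly - c
    norm = np.linalg.norm(d, axis=1, keepdims=True)
    return poly + pad * d / np.maximum(norm, 1e-9)


def interior_region(
    landmarks: np.ndarray, image_dims: tuple[int, int]
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Face-interior mask plus named region polygons.

    Returns ``(mask, regions)`` where ``mask`` is the filled convex hull of
    all template points and ``regions`` maps brows / eyes / nose / mouth /
    cheeks to polygon vertex arrays (clipped subsets of the hull).  Eye and
    mouth interiors are excluded from cheek statistics downstream.
    """
    pts = check_template(landmarks)
    h, w = image_dims
    if pts[:, 0].max() >= w or pts[:, 1].max() >= h or pts.min() < 0:
        raise ValueError("landmarks must lie inside the image")
    hull = _hull(pts)
    mask = _rasterize(hull, (h, w))
    if not mask.any():
        raise ValueError("interior mask is empty")

    scale = np.linalg.norm(eye_centers(pts)[1] - eye_centers(pts)[0]) / 38.0
    pad = 2.0 * scale
    regions: dict[str, np.ndarray] = {}
    regions["brows"] = _expand(
        _hull(np.vstack([group_points(pts, "left_brow"), group_points(pts, "right_brow")])), pad
    )
    regions["eyes"] = _expand(
        _hull(np.vstack([group_points(pts, "left_eye"), group_points(pts, "right_eye")])), pad
    )
    regions["nose"] = _expand(_hull(group_points(pts, "nose")), pad)
    regions["mouth"] = _expand(_hull(group_points(pts, "mouth")), pad)
    # cheeks: two quads spanning eye outer corner -> nose wing -> mouth corner -> jaw side
    jaw = group_points(pts, "jaw")
    nose = group_points(pts, "nose")
    leye = group_points(pts, "left_eye")
    reye = group_points(pts, "right_eye")
    mouth_l = pts[MOUTH_LEFT_CORNER]
    mouth_r = pts[MOUTH_RIGHT_CORNER]
    left_cheek = np.array([leye[0] + (0, 3 * scale), nose[2], mouth_l, jaw[2]])
    right_cheek = np.array([reye[0] + (0, 3 * scale), nose[3], mouth_r, jaw[3]])
    regions["cheeks_left"] = left_cheek
    regions["cheeks_right"] = right_cheek
    # clip polygons into the canvas
    for k, poly in regions.items():
        regions[k] = np.clip(poly, 0, [w - 1, h - 1])
    return mask, regions


def region_masks(
    regions: dict[str, np.ndarray], image_dims: tuple[int, int]
) -> dict[str, np.ndarray]:
    """Rasterize region polygons; merges the two cheek quads into 'cheeks'
    and removes eye/mouth pixels from them (skin measures stay skin-only)."""
    out: dict[str, np.ndarray] = {}
    for name, poly in regions.items():
        out[name] = _rasterize(np.asarray(poly), image_dims)
    if "cheeks_left" in out:
        cheeks = out.pop("cheeks_left") | out.pop("cheeks_right")
        cheeks &= ~(out.get("eyes", False) | out.get("mouth", False))
        out["cheeks"] = cheeks
    return out


# ---------------------------------------------------------------------------
# structure
# ---------------------------------------------------------------------------

def extract_structure(norm: NormalizedLandmarks) -> FeatureVector:
    """Structure features: flattened normalised coordinates + distances."""
    pts = norm.points
    names = [f"{ax}{i:02d}" for i in range(N_LANDMARKS) for ax in ("x", "y")]
    values = list(pts.reshape(-1))

    left_eye_c, right_eye_c = eye_centers(pts)
    lbrow = group_points(pts, "left_brow")
    rbrow = group_points(pts, "right_brow")
    # gap = eye centre y minus brow mean y; y is downward so raising the brow
    # (smaller y) increases the gap
    extras = {
        "brow_eye_gap_left": left_eye_c[1] - lbrow[:, 1].mean(),
        "brow_eye_gap_right": right_eye_c[1] - rbrow[:, 1].mean(),
        "mouth_width": float(
            np.linalg.norm(pts[MOUTH_RIGHT_CORNER] - pts[MOUTH_LEFT_CORNER])
        ),
        # positive when the lip corners sit below the lip centre (frown)
        "mouth_curvature": float(
            (pts[MOUTH_LEFT_CORNER, 1] + pts[MOUTH_RIGHT_CORNER, 1]) / 2
            - (pts[MOUTH_TOP_CENTER, 1] + pts[MOUTH_BOTTOM_CENTER, 1]) / 2
        ),
        "eye_mouth_distance": float(
            np.linalg.norm(
                (left_eye_c + right_eye_c) / 2
                - (pts[MOUTH_TOP_CENTER] + pts[MOUTH_BOTTOM_CENTER]) / 2
            )
        ),
        "nose_length": float(
            np.linalg.norm(
                group_points(pts, "nose")[4] - group_points(pts, "nose")[0]
            )
        ),
    }
    names += list(extras)
    values += list(extras.values())
    return FeatureVector("structure", np.asarray(values), names)


# ---------------------------------------------------------------------------
# color
# ---------------------------------------------------------------------------

_COLOR_REGIONS = ("brows", "eyes", "nose", "mouth", "cheeks")


def extract_color(image: np.ndarray, regions: dict[str, np.ndarray]) -> FeatureVector:
    """Color features: per-region RGB means, CIELAB mean/SD, and contrasts."""
    img = np.asarray(image, dtype=float)
    masks = region_masks(regions, img.shape[:2])
    lab = rgb2lab(img)
    luma = img @ _LUMA

    names: list[str] = []
    values: list[float] = []
    lum_means: dict[str, float] = {}
    for region in _COLOR_REGIONS:
        m = masks[region]
        if not m.any():
            raise ValueError(f"region {region!r} contains zero pixels")
        for ci, ch in enumerate("rgb"):
            names.append(f"{region}_{ch}_mean")
            values.append(float(img[..., ci][m].mean()))
        for ci, ch in enumerate(("L", "a", "b")):
            sub = lab[..., ci][m]
            names += [f"{region}_lab{ch}_mean", f"{region}_lab{ch}_sd"]
            values += [float(sub.mean()) / 100.0, float(sub.std()) / 100.0]
        lum_means[region] = float(luma[m].mean())

    # luminance contrast of the feature regions against cheek skin
    names += ["eye_cheek_contrast", "mouth_cheek_contrast"]
    values += [
        lum_means["cheeks"] - lum_means["eyes"],
        lum_means["cheeks"] - lum_means["mouth"],
    ]
    return FeatureVector("color", np.asarray(values), names)


# ---------------------------------------------------------------------------
# texture
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _gabor_bank(
    orientations: tuple[float, ...] = GABOR_ORIENTATIONS_DEG,
    wavelengths: tuple[float, ...] = GABOR_WAVELENGTHS_PX,
) -> list[tuple[str, np.ndarray]]:
    bank = []
    for wav in wavelengths:
        for theta in orientations:
            k = gabor_kernel(frequency=1.0 / wav, theta=np.deg2rad(theta))
            bank.append((f"wav{int(wav)}_ori{int(theta)}", np.real(k.astype(complex))))
    return bank


def extract_texture(image: np.ndarray, mask: np.ndarray) -> FeatureVector:
    """Texture features: Gabor-bank energies over the masked interior.

    For each filter of the 4-orientation x 3-wavelength bank the features
    are the mean absolute response and the response SD across mask pixels.
    Luminance is mean-centred over the mask first, so a constant image
    yields all-zero energies.
    """
    img = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("texture mask is empty")
    bank = _gabor_bank()
    ksize = max(max(k.shape) for _, k in bank)
    ys, xs = np.nonzero(mask)
    if np.ptp(ys) + 1 < ksize or np.ptp(xs) + 1 < ksize:
        raise ValueError(
            f"mask extent smaller than the largest filter support ({ksize} px)"
        )
    luma = img @ _LUMA if img.ndim == 3 else img
    centered = luma - luma[mask].mean()

    names: list[str] = []
    values: list[float] = []
    for label, kernel in bank:
        resp = fftconvolve(centered, kernel, mode="same")
        sub = resp[mask]
        names += [f"gabor_{label}_absmean", f"gabor_{label}_sd"]
        values += [float(np.abs(sub).mean()), float(sub.std())]
    return FeatureVector("texture", np.asarray(values), names)


# ---------------------------------------------------------------------------
# batch convenience
# ---------------------------------------------------------------------------

def extract_all(record) -> dict[str, FeatureVector]:
    """Extract the full triad for one :class:`~facetriad.synthgen.FaceRecord`."""
    norm = normalize_landmarks(record.landmarks)
    mask, regions = interior_region(record.landmarks, record.image.shape[:2])
    return {
        "structure": extract_structure(norm),
        "color": extract_color(record.image, regions),
        "texture": extract_texture(record.image, mask),
    }


def feature_table(records, metric: str):
    """DataFrame of one metric's features across records (rows = face_id)."""
    import pandas as pd

    rows = {}
    names = None
    for rec in records:
        if metric == "structure":
            fv = extract_structure(normalize_landmarks(rec.landmarks))
        elif metric == "color":
            _, regions = interior_region(rec.landmarks, rec.image.shape[:2])
            fv = extract_color(rec.image, regions)
        elif metric == "texture":
            mask, _ = interior_region(rec.landmarks, rec.image.shape[:2])
            fv = extract_texture(rec.image, mask)
        else:
            raise ValueError(f"unknown metric {metric!r}")
        rows[rec.face_id] = fv.values
        names = fv.feature_names
    return pd.DataFrame.from_dict(rows, orient="index", columns=names)
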
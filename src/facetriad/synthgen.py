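"""Synthetic face cohorts with known planted structure.

Faces are drawn procedurally (filled ellipses, polylines, smooth cheek
gradients, band-limited surface noise) on top of the fixed 42-point landmark
template.  Emotion expressions are realised as three planted channels:

* **shape** — per-landmark-group 2D displacement fields (brows down/in for
  anger, brows up for fear, lip corners up for happiness, ...);
* **color** — per-region additive RGB shifts (e.g. redder cheeks for anger);
* **texture** — changes in the amplitude of the band-limited surface noise.

A gender covariate shifts male faces' geometry/color/texture slightly, and a
*confound specification* additionally moves one gender's **neutral** faces
toward a chosen emotion's displacement/color/texture fields with a tunable
scale — emulating the visual gender-emotion confound (male neutrals
anger-like, female neutrals fear-like) that the downstream analyses are
designed to detect.

All randomness flows from one integer seed; each face uses an independent
substream keyed by its position in the cohort, so cohorts are
order-independent and byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.draw import disk, ellipse, line, polygon

from facetriad import EMOTIONS, TRAITS
from facetriad.template import (
    GROUP_NAMES,
    GROUP_SLICES,
    N_LANDMARKS,
    REFERENCE_SIZE,
    group_points,
    template_points,
)

GENDERS = ("female", "male")

# ---------------------------------------------------------------------------
# planted signal defaults
# ---------------------------------------------------------------------------

# per-group mean displacements (dx, dy) in reference pixels, y downward.
# Signs follow textbook action tendencies; magnitudes are free parameters.
DEFAULT_EMOTION_DISPLACEMENTS: dict[str, dict[str, tuple[float, float]]] = {
    "neutral": {},
    "anger": {  # brows lowered and drawn inward, lips pressed
        "left_brow": (2.0, 3.0),
        "right_brow": (-2.0, 3.0),
        "mouth": (0.0, 1.0),
    },
    "disgust": {  # nose wrinkled upward, brows slightly lowered, upper lip raised
        "nose": (0.0, -3.0),
        "left_brow": (0.0, 2.0),
        "right_brow": (0.0, 2.0),
        "mouth": (0.0, -1.5),
    },
    "fear": {  # brows raised, eyes widened, mouth slightly open
        "left_brow": (0.0, -4.0),
        "right_brow": (0.0, -4.0),
        "left_eye": (0.0, -1.0),
        "right_eye": (0.0, -1.0),
        "mouth": (0.0, 2.0),
    },
    "happy": {  # lip corners up, cheeks raised
        "mouth": (0.0, -3.0),
        "jaw": (0.0, -1.0),
    },
    "sad": {  # mouth corners down, inner brows up a touch
        "mouth": (0.0, 3.0),
        "left_brow": (1.0, -1.0),
        "right_brow": (-1.0, -1.0),
    },
    "surprise": {  # brows high, jaw dropped
        "left_brow": (0.0, -5.0),
        "right_brow": (0.0, -5.0),
        "mouth": (0.0, 4.0),
        "jaw": (0.0, 2.5),
    },
}

# per-region additive RGB shifts, channel units in [0, 1]
DEFAULT_EMOTION_COLOR_SHIFTS: dict[str, dict[str, tuple[float, float, float]]] = {
    "neutral": {},
    "anger": {"cheeks": (0.06, -0.02, -0.02)},
    "disgust": {"cheeks": (-0.02, 0.03, -0.02)},
    "fear": {"cheeks": (-0.04, -0.04, -0.01)},
    "happy": {"cheeks": (0.04, 0.01, 0.00), "mouth": (0.04, -0.01, -0.01)},
    "sad": {"cheeks": (-0.02, -0.02, 0.03)},
    "surprise": {"cheeks": (0.02, 0.02, 0.02)},
}

# additive change to the band-limited noise amplitude (channel units)
DEFAULT_EMOTION_TEXTURE_SHIFTS: dict[str, float] = {
    "neutral": 0.0,
    "anger": 0.020,
    "disgust": 0.015,
    "fear": 0.004,
    "happy": 0.010,
    "sad": 0.007,
    "surprise": 0.012,
}

# per-emotion correlation scale (sigma_y, sigma_x) of the surface noise, in
# reference pixels: each expression leaves a distinct spatial-frequency /
# orientation signature that the Gabor bank can pick up
DEFAULT_EMOTION_TEXTURE_SIGMA: dict[str, tuple[float, float]] = {
    "neutral": (1.2, 1.2),
    "anger": (0.7, 0.7),      # fine, rough grain
    "disgust": (0.9, 1.8),    # horizontally stretched
    "fear": (2.0, 2.0),       # smooth
    "happy": (1.8, 0.9),      # vertically stretched
    "sad": (3.5, 3.5),        # very smooth
    "surprise": (0.5, 1.0),
}

DEFAULT_GENDER_SHAPE_OFFSET: dict[str, tuple[float, float]] = {
    # applied to male faces: slightly lower brows, longer jaw
    "left_brow": (0.0, 1.0),
    "right_brow": (0.0, 1.0),
    "jaw": (0.0, 1.5),
}
DEFAULT_GENDER_COLOR_OFFSET: dict[str, tuple[float, float, float]] = {
    # male skin drawn slightly darker / less red
    "cheeks": (-0.03, -0.03, -0.02),
}
DEFAULT_GENDER_TEXTURE_OFFSET: float = 0.008

#: subtle gender-emotion confound on neutral faces: male neutrals shifted
#: halfway toward the anger fields, female neutrals halfway toward fear
DEFAULT_CONFOUND_SPEC: dict[str, dict[str, float]] = {
    "male": {"anger": 0.5},
    "female": {"fear": 0.5},
}


@dataclass
class FaceGenParams:
    """Parameters of the procedural face generator.

    All displacement magnitudes are reference-canvas pixels (canvas 128);
    they are scaled with ``image_size``.  SDs must be nonnegative and
    ``image_size`` at least 64.
    """

    n_landmarks: int = N_LANDMARKS
    emotion_displacements: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EMOTION_DISPLACEMENTS.items()}
    )
    emotion_color_shifts: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EMOTION_COLOR_SHIFTS.items()}
    )
    emotion_texture_shifts: dict = field(
        default_factory=lambda: dict(DEFAULT_EMOTION_TEXTURE_SHIFTS)
    )
    emotion_texture_sigma: dict = field(
        default_factory=lambda: dict(DEFAULT_EMOTION_TEXTURE_SIGMA)
    )
    gender_shape_offset: dict = field(
        default_factory=lambda: dict(DEFAULT_GENDER_SHAPE_OFFSET)
    )
    gender_color_offset: dict = field(
        default_factory=lambda: dict(DEFAULT_GENDER_COLOR_OFFSET)
    )
    gender_texture_offset: float = DEFAULT_GENDER_TEXTURE_OFFSET
    idiosyncrasy_sd: float = 0.8
    pixel_noise_sd: float = 0.01
    base_texture_amp: float = 0.02
    image_size: int = REFERENCE_SIZE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if self.n_landmarks != N_LANDMARKS:
            raise ValueError(f"template is fixed at {N_LANDMARKS} landmarks")
        for name, val in (
            ("idiosyncrasy_sd", self.idiosyncrasy_sd),
            ("pixel_noise_sd", self.pixel_noise_sd),
            ("base_texture_amp", self.base_texture_amp),
        ):
            if val < 0:
                raise ValueError(f"{name} must be >= 0")
        missing = set(EMOTIONS) - set(self.emotion_displacements)
        if missing:
            raise ValueError(f"emotion_displacements missing classes: {sorted(missing)}")
        unknown = set(self.emotion_displacements) - set(EMOTIONS)
        if unknown:
            raise ValueError(f"unknown emotion classes: {sorted(unknown)}")


@dataclass
class FaceRecord:
    """One face flowing through the pipeline: raster + landmarks + metadata."""

    image: np.ndarray  # (H, W, 3) float in [0, 1]
    landmarks: np.ndarray  # (42, 2) float, pixel coords, x rightward / y downward
    face_id: str
    gender: str
    emotion: str = "unlabeled"

    def __post_init__(self) -> None:
        h, w = self.image.shape[:2]
        if not np.all(np.isfinite(self.landmarks)):
            raise ValueError("landmarks must be finite")
        x, y = self.landmarks[:, 0], self.landmarks[:, 1]
        if x.min() < 0 or y.min() < 0 or x.max() >= w or y.max() >= h:
            raise ValueError(f"landmarks of {self.face_id} fall outside the image bounds")


# ---------------------------------------------------------------------------
# displacement helpers
# ---------------------------------------------------------------------------

def displacement_field(spec: Mapping[str, Sequence[float]], scale: float = 1.0) -> np.ndarray:
    """Expand a per-group offset mapping into a (42, 2) per-landmark field."""
    out = np.zeros((N_LANDMARKS, 2))
    for group, (dx, dy) in spec.items():
        if group not in GROUP_SLICES:
            raise ValueError(f"unknown landmark group {group!r}")
        out[GROUP_SLICES[group]] = (dx, dy)
    return out * scale


def confound_fields(
    params: FaceGenParams, confound_spec: Mapping[str, Mapping[str, float]] | None
) -> dict[str, dict]:
    """Planted neutral-face shift per gender: the generator's own ground truth.

    ``confound_spec`` maps gender -> {emotion: scale}; the applied shape field
    is ``scale x`` that emotion's displacement field (reference pixels), and
    the color/texture shifts are scaled the same way.  Returned per gender:
    ``{"shape": (42,2) array, "color": {region: rgb}, "texture": float}``.
    """
    fields: dict[str, dict] = {
        g: {"shape": np.zeros((N_LANDMARKS, 2)), "color": {}, "texture": 0.0}
        for g in GENDERS
    }
    if not confound_spec:
        return fields
    for gender, shifts in confound_spec.items():
        if gender not in GENDERS:
            raise ValueError(f"unknown gender {gender!r} in confound_spec")
        for emotion, scale in shifts.items():
            if emotion not in EMOTIONS:
                raise ValueError(f"unknown emotion {emotion!r} in confound_spec")
            fields[gender]["shape"] = fields[gender]["shape"] + displacement_field(
                params.emotion_displacements.get(emotion, {}), scale
            )
            for region, rgb in params.emotion_color_shifts.get(emotion, {}).items():
                prev = np.asarray(fields[gender]["color"].get(region, (0.0, 0.0, 0.0)))
                fields[gender]["color"][region] = tuple(prev + scale * np.asarray(rgb))
            fields[gender]["texture"] += scale * params.emotion_texture_shifts.get(emotion, 0.0)
    return fields


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_SKIN = np.array([0.78, 0.62, 0.52])
_LIP = np.array([0.66, 0.36, 0.36])
_BROW = np.array([0.28, 0.20, 0.14])
_IRIS = np.array([0.25, 0.18, 0.12])
_SCLERA = np.array([0.93, 0.93, 0.92])
_BG = 0.82


def _cheek_region_masks(landmarks: np.ndarray, size: int) -> dict[str, np.ndarray]:
    """Boolean pixel masks for the paintable regions (cheeks, mouth, eyes, nose)."""
    s = size / REFERENCE_SIZE
    masks: dict[str, np.ndarray] = {}
    yy, xx = np.mgrid[0:size, 0:size]
    # cheeks: two soft disks centred between eye and mouth corner on each side
    left = (group_points(landmarks, "left_eye").mean(axis=0)
            + landmarks[GROUP_SLICES["mouth"].start]) / 2 + np.array([-4 * s, 0])
    right = (group_points(landmarks, "right_eye").mean(axis=0)
             + landmarks[GROUP_SLICES["mouth"].start + 4]) / 2 + np.array([4 * s, 0])
    r = 13 * s
    masks["cheeks"] = ((xx - left[0]) ** 2 + (yy - left[1]) ** 2 <= r**2) | (
        (xx - right[0]) ** 2 + (yy - right[1]) ** 2 <= r**2
    )
    for region, group in (("mouth", "mouth"), ("nose", "nose")):
        pts = group_points(landmarks, group)
        hull = _convex_hull(pts)
        rr, cc = polygon(hull[:, 1], hull[:, 0], (size, size))
        m = np.zeros((size, size), dtype=bool)
        m[rr, cc] = True
        masks[region] = m
    eye = np.zeros((size, size), dtype=bool)
    for g in ("left_eye", "right_eye"):
        c = group_points(landmarks, g).mean(axis=0)
        rr, cc = ellipse(c[1], c[0], 4 * s, 7 * s, (size, size))
        eye[rr, cc] = True
    masks["eyes"] = eye
    return masks


def _convex_hull(pts: np.ndarray) -> np.ndarray:
    from scipy.spatial import ConvexHull

    hull = ConvexHull(pts)
    return pts[hull.vertices]


def render_face(
    landmarks: np.ndarray,
    size: int,
    skin_shift: Mapping[str, Sequence[float]] | None = None,
    texture_amp: float = 0.02,
    texture_sigma: tuple[float, float] = (1.2, 1.2),
    pixel_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw a face for the given landmark set; deterministic given ``rng``."""
    rng = rng or np.random.default_rng(0)
    s = size / REFERENCE_SIZE
    img = np.full((size, size, 3), _BG)

    # head: filled ellipse with a gentle vertical shading gradient
    cy, cx = 70 * s, 64 * s
    rr, cc = ellipse(cy, cx, 54 * s, 42 * s, (size, size))
    head = np.zeros((size, size), dtype=bool)
    head[rr, cc] = True
    shade_col = 1.0 - 0.15 * ((np.arange(size) - cy) / (54 * s)) ** 2
    shade = np.repeat(shade_col[:, None], size, axis=1)
    img[head] = _SKIN[None, :] * shade[head][:, None]

    # soft rosy cheek gradient baked into the skin
    masks = _cheek_region_masks(landmarks, size)
    img[masks["cheeks"] & head] += np.array([0.03, 0.0, 0.0])

    # region color shifts (emotion / gender / confound), applied within head
    if skin_shift:
        for region, rgb in skin_shift.items():
            if region not in masks:
                raise ValueError(f"unknown color region {region!r}")
            img[masks[region] & head] += np.asarray(rgb, dtype=float)

    # brows: thick dark polylines
    for g in ("left_brow", "right_brow"):
        pts = group_points(landmarks, g)
        for a, b in zip(pts[:-1], pts[1:]):
            rr, cc = line(int(round(a[1])), int(round(a[0])), int(round(b[1])), int(round(b[0])))
            ok = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
            for dy in range(-int(np.ceil(1.5 * s)), int(np.ceil(1.5 * s)) + 1):
                rr2 = np.clip(rr[ok] + dy, 0, size - 1)
                img[rr2, cc[ok]] = _BROW

    # eyes: sclera ellipse sized by lid opening + iris disk
    for g in ("left_eye", "right_eye"):
        pts = group_points(landmarks, g)
        c = pts.mean(axis=0)
        half_h = max((pts[:, 1].max() - pts[:, 1].min()) / 2, 1.0)
        half_w = max((pts[:, 0].max() - pts[:, 0].min()) / 2, 2.0)
        rr, cc = ellipse(c[1], c[0], half_h, half_w, (size, size))
        img[rr, cc] = _SCLERA
        rr, cc = disk((c[1], c[0]), max(half_h * 0.8, 1.0), shape=(size, size))
        img[rr, cc] = _IRIS

    # nose: darker polyline bridge->tip and wing-to-wing shading
    nose = group_points(landmarks, "nose")
    for a, b in ((nose[0], nose[1]), (nose[2], nose[4]), (nose[3], nose[4])):
        rr, cc = line(int(round(a[1])), int(round(a[0])), int(round(b[1])), int(round(b[0])))
        ok = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
        img[rr[ok], cc[ok]] *= 0.85

    # mouth: filled outer-lip polygon
    mouth_outer = group_points(landmarks, "mouth")[:8]
    rr, cc = polygon(mouth_outer[:, 1], mouth_outer[:, 0], (size, size))
    img[rr, cc] = _LIP

    # band-limited surface noise (texture) restricted to the head
    if texture_amp > 0:
        noise = rng.standard_normal((size, size))
        noise = ndimage.gaussian_filter(
            noise, sigma=(texture_sigma[0] * s, texture_sigma[1] * s)
        )
        noise /= max(noise.std(), 1e-12)
        img[head] += (texture_amp * noise[head])[:, None]
    else:
        # keep the substream aligned whether or not texture is drawn
        rng.standard_normal((size, size))

    # pixel noise over the whole image
    if pixel_noise_sd > 0:
        img += rng.normal(0.0, pixel_noise_sd, img.shape)

    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _merge_color(*shifts: Mapping[str, Sequence[float]]) -> dict[str, tuple]:
    out: dict[str, np.ndarray] = {}
    for shift in shifts:
        for region, rgb in (shift or {}).items():
            out[region] = out.get(region, np.zeros(3)) + np.asarray(rgb, dtype=float)
    return {k: tuple(v) for k, v in out.items()}


def make_face(
    params: FaceGenParams,
    emotion: str,
    gender: str,
    face_id: str,
    substream: int,
    confound: Mapping[str, dict] | None = None,
) -> FaceRecord:
    """Render a single face from an independent counter-keyed substream."""
    rng = np.random.default_rng([params.seed, substream])
    s = params.image_size / REFERENCE_SIZE

    pts = template_points(params.image_size)
    shift = displacement_field(params.emotion_displacements[emotion]) * s
    color = dict(params.emotion_color_shifts.get(emotion, {}))
    texture = params.base_texture_amp + params.emotion_texture_shifts.get(emotion, 0.0)

    if gender == "male":
        shift = shift + displacement_field(params.gender_shape_offset) * s
        color = _merge_color(color, params.gender_color_offset)
        texture += params.gender_texture_offset

    if confound is not None and emotion == "neutral":
        fields = confound[gender]
        shift = shift + fields["shape"] * s
        color = _merge_color(color, fields["color"])
        texture += fields["texture"]

    pts = pts + shift
    if params.idiosyncrasy_sd > 0:
        pts = pts + rng.normal(0.0, params.idiosyncrasy_sd * s, pts.shape)
    else:
        rng.normal(0.0, 1.0, pts.shape)  # keep substream aligned

    img = render_face(
        pts,
        params.image_size,
        skin_shift=color,
        texture_amp=max(texture, 0.0),
        texture_sigma=params.emotion_texture_sigma.get(emotion, (1.2, 1.2)),
        pixel_noise_sd=params.pixel_noise_sd,
        rng=rng,
    )
    pts = np.clip(pts, 0.0, params.image_size - 1.0)
    return FaceRecord(image=img, landmarks=pts, face_id=face_id, gender=gender, emotion=emotion)


def make_cohort(
    params: FaceGenParams,
    n_per_cell: int,
    confound_spec: Mapping[str, Mapping[str, float]] | None = None,
    seed: int | None = None,
) -> tuple[list[FaceRecord], pd.DataFrame, dict]:
    """Generate a balanced emotion x gender cohort.

    Returns ``(records, metadata, manifest)``.  The manifest stores the
    planted per-gender neutral-face confound fields (the ground truth used
    by recovery tests), the parameters, and the seed.
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    if seed is not None:
        params = dataclasses.replace(params, seed=seed)
    confound = confound_fields(params, confound_spec)

    records: list[FaceRecord] = []
    rows = []
    stream = 0
    for emotion in EMOTIONS:
        for gender in GENDERS:
            for i in range(n_per_cell):
                face_id = f"{emotion[:3]}_{gender[0]}_{i:04d}"
                rec = make_face(params, emotion, gender, face_id, stream, confound)
                records.append(rec)
                rows.append({"face_id": face_id, "gender": gender, "emotion": emotion})
                stream += 1
    metadata = pd.DataFrame(rows)
    manifest = {
        "seed": params.seed,
        "n_per_cell": n_per_cell,
        "image_size": params.image_size,
        "confound_spec": {g: dict(v) for g, v in (confound_spec or {}).items()},
        "planted_neutral_shift": {
            g: {
                "shape": confound[g]["shape"].tolist(),
                "color": {k: list(v) for k, v in confound[g]["color"].items()},
                "texture": confound[g]["texture"],
            }
            for g in GENDERS
        },
    }
    return records, metadata, manifest


# ---------------------------------------------------------------------------
# rating tables
# ---------------------------------------------------------------------------

@dataclass
class RatingModel:
    """Linear map from latent (dominance, affiliation) to trait means.

    ``trait_weights`` maps each trait to ``(w_dominance, w_affiliation)``;
    ratings are ``intercept + w_d*D + w_a*A + N(0, noise_sd)``.  Masculinity
    is generated from latent dominance; femininity is its mirror plus
    ``fem_mirror_noise_sd`` noise, reproducing the strongly negative
    masculinity-femininity correlation of normed rating sets.
    """

    trait_weights: dict = field(
        default_factory=lambda: {
            "angry": (0.8, -0.4),
            "happy": (0.0, 0.9),
            "trustworthy": (-0.3, 0.8),
            "dominant": (1.0, 0.0),
            "healthy": (0.2, 0.4),
            "attractive": (0.0, 0.3),
            "babyish": (-0.7, 0.2),
            "smart": (0.1, 0.1),
        }
    )
    intercept: float = 4.0
    noise_sd: float = 0.3
    masc_weight: float = 1.0
    fem_mirror_noise_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.fem_mirror_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")


def make_ratings(
    metadata: pd.DataFrame,
    rating_model: RatingModel | None = None,
    seed: int = 0,
    latents: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Rating table: per-face trait means as a planted linear model + noise.

    Latent dominance/affiliation default to standard normals with a gender
    mean shift (+0.5 dominance for male faces); pass ``latents`` (columns
    ``latent_dominance``/``latent_affiliation`` indexed like metadata rows)
    to plant specific values.
    """
    model = rating_model or RatingModel()
    rng = np.random.default_rng(seed)
    n = len(metadata)
    if n == 0:
        raise ValueError("metadata is empty")
    if latents is None:
        d = rng.standard_normal(n) + 0.5 * (metadata["gender"].to_numpy() == "male")
        a = rng.standard_normal(n) - 0.3 * (metadata["gender"].to_numpy() == "male")
    else:
        d = np.asarray(latents["latent_dominance"], dtype=float)
        a = np.asarray(latents["latent_affiliation"], dtype=float)
        if len(d) != n:
            raise ValueError("latents length does not match metadata")

    out = pd.DataFrame({"face_id": metadata["face_id"].to_numpy()})
    out["latent_dominance"] = d
    out["latent_affiliation"] = a
    for trait in TRAITS:
        wd, wa = model.trait_weights.get(trait, (0.0, 0.0))
        out[trait] = model.intercept + wd * d + wa * a + rng.normal(0, model.noise_sd, n)
    masc = model.intercept + model.masc_weight * d + rng.normal(0, model.noise_sd, n)
    out["masculinity"] = masc
    out["femininity"] = (
        2 * model.intercept - masc + rng.normal(0, model.fem_mirror_noise_sd, n)
    )
    return out


# ---------------------------------------------------------------------------
# trial tables
# ---------------------------------------------------------------------------

@dataclass
class TrialContamination:
    """Counts of planted preprocessing violations."""

    n_low_sd_participants: int = 0
    n_fast_trials: int = 0
    n_slow_trials: int = 0
    fast_rt_ms: float = 20.0
    slow_rt_ms: float = 20000.0


def make_trials(
    ratings: pd.DataFrame,
    n_participants: int = 20,
    contamination: TrialContamination | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Participant x face x trait trial table with plantable violations.

    Responses are the rounded rating-table trait means plus participant
    noise, clipped to 1-7; reaction times are log-normal around ~1.2 s.
    ``contamination`` plants participants whose responses barely vary
    (response SD ~0.1, below the 0.4 exclusion threshold) and trials with
    out-of-range reaction times *among the retained participants*.  The
    returned manifest lists exactly which rows violate which filter.
    """
    cont = contamination or TrialContamination()
    if cont.n_low_sd_participants > n_participants:
        raise ValueError("more low-SD participants requested than participants")
    rng = np.random.default_rng(seed)

    face_ids = ratings["face_id"].to_numpy()
    rows = []
    low_sd_participants = [f"p{idx:03d}" for idx in range(cont.n_low_sd_participants)]
    for p_idx in range(n_participants):
        pid = f"p{p_idx:03d}"
        low_var = p_idx < cont.n_low_sd_participants
        for fid in face_ids:
            face_row = ratings.loc[ratings["face_id"] == fid].iloc[0]
            for trait in TRAITS:
                if low_var:
                    resp = 4 + int(rng.random() < 0.01)  # SD ~ 0.1
                else:
                    resp = int(np.clip(round(face_row[trait] + rng.normal(0, 1.0)), 1, 7))
                rt = float(rng.lognormal(mean=7.0, sigma=0.35))  # ~1.1 s median
                rt = float(np.clip(rt, 200.0, 8000.0))
                rows.append((pid, fid, trait, resp, rt))
    trials = pd.DataFrame(
        rows, columns=["participant_id", "face_id", "trait", "response", "rt_ms"]
    )

    retained = ~trials["participant_id"].isin(low_sd_participants)
    idx_pool = trials.index[retained].to_numpy()
    n_bad = cont.n_fast_trials + cont.n_slow_trials
    if n_bad > len(idx_pool):
        raise ValueError("more contaminated trials requested than retained trials")
    bad = rng.choice(idx_pool, size=n_bad, replace=False)
    fast_idx = np.sort(bad[: cont.n_fast_trials])
    slow_idx = np.sort(bad[cont.n_fast_trials:])
    trials.loc[fast_idx, "rt_ms"] = cont.fast_rt_ms
    trials.loc[slow_idx, "rt_ms"] = cont.slow_rt_ms

    manifest = {
        "seed": seed,
        "low_sd_participants": low_sd_participants,
        "fast_trial_rows": [int(i) for i in fast_idx],
        "slow_trial_rows": [int(i) for i in slow_idx],
        "n_participants": n_participants,
        "n_trials": len(trials),
    }
    return trials, manifest


# ---------------------------------------------------------------------------
# disk I/O
# ---------------------------------------------------------------------------

def save_record(rec: FaceRecord, outdir: str | Path) -> None:
    """Write ``<face_id>.png`` and ``<face_id>.landmarks.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    arr = np.clip(np.round(rec.image * 255), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(outdir / f"{rec.face_id}.png")
    with open(outdir / f"{rec.face_id}.landmarks.json", "w") as fh:
        json.dump(rec.landmarks.tolist(), fh)


def load_record(outdir: str | Path, face_id: str, gender: str = "unlabeled",
                emotion: str = "unlabeled") -> FaceRecord:
    outdir = Path(outdir)
    img = np.asarray(Image.open(outdir / f"{face_id}.png"), dtype=float) / 255.0
    with open(outdir / f"{face_id}.landmarks.json") as fh:
        pts = np.asarray(json.load(fh), dtype=float)
    return FaceRecord(image=img, landmarks=pts, face_id=face_id, gender=gender, emotion=emotion)
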
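"""Landmark-based face morphing: 50-50 shape/color blends.

A transform blends a close-to-origin base face with a prototype donor:
landmarks are averaged pointwise and both images are piecewise-affinely
warped onto the average shape over a *fixed* Delaunay triangulation of the
mean template (computed once and reused for every warp, so triangle
topology never flips between faces), then pixel-averaged.  Pixels outside
all triangles pass through unchanged; interpolation is bilinear and
out-of-gamut values are clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.spatial import Delaunay
from skimage.draw import polygon as draw_polygon

from facetriad.synthgen import FaceRecord
from facetriad.template import N_LANDMARKS, check_template, template_points


@dataclass
class MorphSpec:
    """One planned blend: base, donor, mixing proportion, output id."""

    base_id: str
    donor_id: str
    alpha: float = 0.5
    output_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


@lru_cache(maxsize=4)
def _template_triangles(image_size: int = 128) -> np.ndarray:
    """Delaunay simplices (triples of landmark indices) of the mean template."""
    tri = Delaunay(template_points(image_size))
    return tri.simplices.copy()


def average_shape(
    landmarks_a: np.ndarray, landmarks_b: np.ndarray, alpha: float = 0.5
) -> np.ndarray:
    """Pointwise blend ``(1 - alpha) * a + alpha * b``."""
    a = check_template(landmarks_a)
    b = check_template(landmarks_b)
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return (1.0 - alpha) * a + alpha * b


def warp(
    image: np.ndarray, src_landmarks: np.ndarray, dst_landmarks: np.ndarray
) -> np.ndarray:
    """Piecewise-affine warp of ``image`` from src onto dst landmarks.

    For each triangle of the fixed template triangulation, the affine map
    dst -> src is solved and destination pixels are sampled bilinearly from
    the source.  Pixels outside every destination triangle keep their
    original values.
    """
    img = np.asarray(image, dtype=float)
    src = check_template(src_landmarks)
    dst = check_template(dst_landmarks)
    h, w = img.shape[:2]
    if dst[:, 0].max() >= w or dst[:, 1].max() >= h or dst.min() < 0:
        raise ValueError("destination landmarks must lie inside the canvas")
    out = img.copy()
    for t_idx, tri in enumerate(_template_triangles()):
        d = dst[tri]  # (3, 2) destination triangle
        s = src[tri]
        u, v = d[1] - d[0], d[2] - d[0]
        area = 0.5 * abs(u[0] * v[1] - u[1] * v[0])
        if area < 1e-9:
            raise ValueError(f"degenerate (zero-area) destination triangle {t_idx}")
        rr, cc = draw_polygon(d[:, 1], d[:, 0], (h, w))
        if rr.size == 0:
            continue
        # affine A @ [x, y, 1] mapping dst -> src
        M = np.column_stack([d, np.ones(3)])
        A = np.linalg.solve(M, s)  # (3, 2): [x, y, 1] @ A = src (x, y)
        sx = cc * A[0, 0] + rr * A[1, 0] + A[2, 0]
        sy = cc * A[0, 1] + rr * A[1, 1] + A[2, 1]
        for ch in range(img.shape[2]) if img.ndim == 3 else [None]:
            plane = img[..., ch] if ch is not None else img
            vals = map_coordinates(plane, [sy, sx], order=1, mode="nearest")
            if ch is not None:
                out[rr, cc, ch] = vals
            else:
                out[rr, cc] = vals
    return out


def blend_transform(base: FaceRecord, donor: FaceRecord, alpha: float = 0.5,
                    output_id: str | None = None) -> FaceRecord:
    """Blend a base face with a donor at proportion ``alpha`` (default 50-50).

    Output landmarks are the pointwise shape average; the output image is
    the alpha-weighted mean of both faces warped onto that average shape.
    Base and donor must be gender-matched.
    """
    if base.gender != donor.gender:
        raise ValueError(
            f"gender mismatch: base {base.gender!r} vs donor {donor.gender!r}"
        )
    avg = average_shape(base.landmarks, donor.landmarks, alpha)
    img = (1.0 - alpha) * warp(base.image, base.landmarks, avg) + alpha * warp(
        donor.image, donor.landmarks, avg
    )
    return FaceRecord(
        image=np.clip(img, 0.0, 1.0),
        landmarks=avg,
        face_id=output_id or f"{base.face_id}+{donor.face_id}@{alpha:g}",
        gender=base.gender,
        emotion="unlabeled",
    )


def qc_flags(rec: FaceRecord) -> list[str]:
    """Automated artifact checks replacing manual visual inspection."""
    flags = []
    h, w = rec.image.shape[:2]
    x, y = rec.landmarks[:, 0], rec.landmarks[:, 1]
    if x.min() < 0 or y.min() < 0 or x.max() >= w or y.max() >= h:
        flags.append("landmarks_out_of_bounds")
    if rec.image.min() < -1e-9 or rec.image.max() > 1 + 1e-9:
        flags.append("luminance_out_of_range")
    if rec.image.std() < 1e-3:
        flags.append("degenerate_image")
    return flags


def build_stimulus_set(
    bases: list[FaceRecord],
    pools: dict[str, list[FaceRecord]],
    reps_per_category: int = 4,
    alpha: float = 0.5,
    seed: int = 0,
) -> tuple[list[FaceRecord], pd.DataFrame]:
    """Morph every base with donors sampled from each category pool.

    For each base x category, ``reps_per_category`` gender-matched donors
    are sampled without replacement (with replacement only when the pool is
    too small, flagged in the manifest).  Output count is
    ``len(bases) * len(pools) * reps_per_category``.
    """
    rng = np.random.default_rng(seed)
    for cat, pool in pools.items():
        if not pool:
            raise ValueError(f"pool for category {cat!r} is empty")
    records: list[FaceRecord] = []
    rows = []
    for base in bases:
        for cat in sorted(pools):
            matched = [d for d in pools[cat] if d.gender == base.gender]
            if not matched:
                raise ValueError(
                    f"no gender-matched donors in pool {cat!r} for base {base.face_id}"
                )
            replace = len(matched) < reps_per_category
            donors = rng.choice(
                len(matched), size=reps_per_category, replace=replace
            )
            for rep, di in enumerate(donors):
                donor = matched[di]
                out_id = f"morph_{base.face_id}_{cat}_{rep}"
                rec = blend_transform(base, donor, alpha, output_id=out_id)
                records.append(rec)
                rows.append(
                    {
                        "output_id": out_id,
                        "base_id": base.face_id,
                        "donor_id": donor.face_id,
                        "category": cat,
                        "rep": rep,
                        "alpha": alpha,
                        "gender": base.gender,
                        "pool_exhausted": replace,
                        "qc_flags": ";".join(qc_flags(rec)),
                        "seed": seed,
                    }
                )
    return records, pd.DataFrame(rows)
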
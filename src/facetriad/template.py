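"""Fixed 42-point facial landmark template shared by the generator and the
feature extractors.

The template covers the interior of the face only: 10 brow points, 8 eye
points, 5 nose points, 12 mouth points, and 7 jaw/cheek interior points.
Coordinates are pixels in a 128x128 reference canvas, 0-based, x rightward,
y downward; generators scale the template to other canvas sizes.
"""

from __future__ import annotations

import numpy as np

REFERENCE_SIZE = 128

#: canonical group order; landmark order is the concatenation of these groups
GROUP_NAMES = (
    "left_brow",
    "right_brow",
    "left_eye",
    "right_eye",
    "nose",
    "mouth",
    "jaw",
)

_TEMPLATE = {
    "left_brow": [(34, 46), (39, 43), (45, 42), (51, 43), (56, 45)],
    "right_brow": [(72, 45), (77, 43), (83, 42), (89, 43), (94, 46)],
    # order per eye: outer corner, top, inner corner, bottom
    "left_eye": [(38, 54), (45, 51), (52, 54), (45, 57)],
    "right_eye": [(90, 54), (83, 51), (76, 54), (83, 57)],
    # bridge, tip, left wing, right wing, base
    "nose": [(64, 60), (64, 72), (57, 74), (71, 74), (64, 78)],
    # outer lip ring (8, from left corner clockwise through top), inner ring (4)
    "mouth": [
        (50, 92), (56, 89), (64, 88), (72, 89), (78, 92), (72, 96),
        (64, 97), (56, 96),
        (57, 92), (64, 91), (71, 92), (64, 93),
    ],
    # cheek sides, lower cheeks, jaw interior, chin
    "jaw": [(34, 58), (94, 58), (36, 78), (92, 78), (46, 102), (82, 102), (64, 112)],
}

N_LANDMARKS = sum(len(v) for v in _TEMPLATE.values())  # 42

#: slice of each group's rows in the (42, 2) landmark array
GROUP_SLICES: dict[str, slice] = {}
_start = 0
for _name in GROUP_NAMES:
    _stop = _start + len(_TEMPLATE[_name])
    GROUP_SLICES[_name] = slice(_start, _stop)
    _start = _stop

#: index of the mouth corners / lip centre within the mouth group
MOUTH_LEFT_CORNER = GROUP_SLICES["mouth"].start + 0
MOUTH_RIGHT_CORNER = GROUP_SLICES["mouth"].start + 4
MOUTH_TOP_CENTER = GROUP_SLICES["mouth"].start + 2
MOUTH_BOTTOM_CENTER = GROUP_SLICES["mouth"].start + 6


def template_points(image_size: int = REFERENCE_SIZE) -> np.ndarray:
    """Return the (42, 2) float template scaled to an ``image_size`` canvas."""
    pts = np.concatenate(
        [np.asarray(_TEMPLATE[name], dtype=float) for name in GROUP_NAMES]
    )
    return pts * (image_size / REFERENCE_SIZE)


def group_points(landmarks: np.ndarray, name: str) -> np.ndarray:
    """Rows of ``landmarks`` belonging to the named group."""
    return np.asarray(landmarks, dtype=float)[GROUP_SLICES[name]]


def eye_centers(landmarks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(left, right) eye centres: the mean of each eye's four points."""
    return (
        group_points(landmarks, "left_eye").mean(axis=0),
        group_points(landmarks, "right_eye").mean(axis=0),
    )


def check_template(landmarks: np.ndarray) -> np.ndarray:
    """Validate shape/finiteness of a landmark set; return a float copy."""
    pts = np.asarray(landmarks, dtype=float)
    if pts.shape != (N_LANDMARKS, 2):
        raise ValueError(
            f"expected {N_LANDMARKS} landmarks with 2 coordinates, got shape {pts.shape}"
        )
    if not np.all(np.isfinite(pts)):
        raise ValueError("landmark coordinates must be finite")
    return pts.copy()
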
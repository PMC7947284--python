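"""Dominance-affiliation face space.

Emotion outputs are projected onto the interpersonal circumplex using
Knutson's per-emotion loadings: dominance is the y axis, affiliation the
x axis, and for an emotion-probability vector I the coordinates are

    D_hat = sum_i Yd_i * I_i        A_hat = sum_i Xa_i * I_i

summed over the six expressive classes (the neutral probability is simply
excluded; the six entries are not renormalised).  Polar position is
``E_hat = sqrt(D^2 + A^2)`` and ``theta = atan2(D, A)`` in degrees wrapped
to [0, 360).  Quadrant membership requires a minimum distance from the
origin (default 0.15) and an angle inside the quadrant's window: QI 10-80,
QII 100-170, QIII 190-260, QIV 280-350 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from facetriad import EMOTIONS_SIX

#: default per-emotion (dominance, affiliation) loadings
DEFAULT_LOADINGS: dict[str, tuple[float, float]] = {
    "anger": (1.0, -1.5),
    "disgust": (0.6, -1.0),
    "happy": (1.0, 2.0),
    "fear": (-0.5, 0.5),
    "sad": (-1.0, 0.1),
    "surprise": (-0.5, 0.1),
}


@dataclass(frozen=True)
class KnutsonCoefficients:
    """Per-emotion dominance (Y^d) and affiliation (X^a) loadings."""

    dominance: Mapping[str, float] = field(
        default_factory=lambda: {e: v[0] for e, v in DEFAULT_LOADINGS.items()}
    )
    affiliation: Mapping[str, float] = field(
        default_factory=lambda: {e: v[1] for e, v in DEFAULT_LOADINGS.items()}
    )

    def __post_init__(self) -> None:
        for name, table in (("dominance", self.dominance), ("affiliation", self.affiliation)):
            if set(table) != set(EMOTIONS_SIX):
                raise ValueError(
                    f"{name} loadings must cover exactly the six emotions {EMOTIONS_SIX}"
                )


@dataclass
class QuadrantWindows:
    """Inclusive angle windows (degrees) and minimum origin distance."""

    windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "I": (10.0, 80.0),
            "II": (100.0, 170.0),
            "III": (190.0, 260.0),
            "IV": (280.0, 350.0),
        }
    )
    min_distance: float = 0.15

    def __post_init__(self) -> None:
        if self.min_distance < 0:
            raise ValueError("min_distance must be >= 0")
        items = sorted(self.windows.items(), key=lambda kv: kv[1][0])
        for (qa, (lo_a, hi_a)), (qb, (lo_b, hi_b)) in zip(items, items[1:]):
            if hi_a >= lo_b:
                raise ValueError(f"quadrant windows {qa} and {qb} overlap")
        for q, (lo, hi) in self.windows.items():
            if not (0 <= lo <= hi < 360):
                raise ValueError(f"window {q} bounds must satisfy 0 <= lo <= hi < 360")


@dataclass
class FaceSpacePosition:
    """One face's location in dominance-affiliation space."""

    D_hat: float
    A_hat: float
    E_hat: float
    theta_deg: float
    quadrant: str


def _as_emotion_map(I) -> dict[str, float]:
    if isinstance(I, Mapping):
        probs = dict(I)
    elif isinstance(I, pd.Series):
        probs = I.to_dict()
    else:
        arr = np.asarray(I, dtype=float)
        if arr.shape != (len(EMOTIONS_SIX),):
            raise ValueError(
                f"expected a mapping or a length-{len(EMOTIONS_SIX)} vector in order "
                f"{EMOTIONS_SIX}"
            )
        probs = dict(zip(EMOTIONS_SIX, arr))
    missing = set(EMOTIONS_SIX) - set(probs)
    if missing:
        raise ValueError(f"emotion output missing classes: {sorted(missing)}")
    return probs


def project(I, coeffs: KnutsonCoefficients | None = None) -> tuple[float, float]:
    """(D_hat, A_hat) for one emotion output.

    ``I`` may be a mapping (a neutral entry, if present, is ignored), a
    pandas Series, or a length-6 vector in the order ``EMOTIONS_SIX``.
    """
    coeffs = coeffs or KnutsonCoefficients()
    probs = _as_emotion_map(I)
    d = sum(coeffs.dominance[e] * float(probs[e]) for e in EMOTIONS_SIX)
    a = sum(coeffs.affiliation[e] * float(probs[e]) for e in EMOTIONS_SIX)
    return float(d), float(a)


def polar(D_hat: float, A_hat: float) -> tuple[float, float]:
    """(E_hat, theta_deg): distance from the origin and angle in [0, 360).

    The angle is measured from the positive affiliation (x) axis toward
    positive dominance (y); the origin maps to (0, 0).
    """
    if not (np.isfinite(D_hat) and np.isfinite(A_hat)):
        raise ValueError("coordinates must be finite")
    e = float(np.hypot(D_hat, A_hat))
    if e == 0.0:
        return 0.0, 0.0
    theta = float(np.degrees(np.arctan2(D_hat, A_hat))) % 360.0
    return e, theta


def assign_quadrant(
    theta_deg: float, E_hat: float, windows: QuadrantWindows | None = None
) -> str:
    """Quadrant label for a polar position, or "none" outside all windows."""
    windows = windows or QuadrantWindows()
    if not 0.0 <= theta_deg < 360.0:
        raise ValueError("theta_deg must lie in [0, 360)")
    if E_hat <= windows.min_distance:
        return "none"
    for q, (lo, hi) in windows.windows.items():
        if lo <= theta_deg <= hi:
            return q
    return "none"


def position(I, coeffs: KnutsonCoefficients | None = None,
             windows: QuadrantWindows | None = None) -> FaceSpacePosition:
    """Full face-space position for one emotion output."""
    d, a = project(I, coeffs)
    e, theta = polar(d, a)
    return FaceSpacePosition(
        D_hat=d, A_hat=a, E_hat=e, theta_deg=theta,
        quadrant=assign_quadrant(theta, e, windows),
    )


def position_table(
    outputs: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    coeffs: KnutsonCoefficients | None = None,
    windows: QuadrantWindows | None = None,
) -> pd.DataFrame:
    """Face-space positions for a table of emotion outputs (rows = face_id)."""
    rows = []
    for fid, row in outputs.iterrows():
        pos = position(row, coeffs, windows)
        rows.append(
            {
                "face_id": fid,
                "D_hat": pos.D_hat,
                "A_hat": pos.A_hat,
                "E_hat": pos.E_hat,
                "theta_deg": pos.theta_deg,
                "quadrant": pos.quadrant,
            }
        )
    table = pd.DataFrame(rows)
    if metadata is not None:
        table = table.merge(metadata[["face_id", "gender"]], on="face_id", how="left")
    return table


# ---------------------------------------------------------------------------
# stimulus selection
# ---------------------------------------------------------------------------

def _topk(df: pd.DataFrame, by: str, k: int, ascending: bool) -> tuple[list[str], bool]:
    ranked = df.sort_values([by, "face_id"], ascending=[ascending, True])
    flagged = len(ranked) < k
    return list(ranked["face_id"].head(k)), flagged


def select_prototypes(
    positions: pd.DataFrame,
    k: int = 20,
    windows: QuadrantWindows | None = None,
    mode: str = "quadrant",
    emotion_outputs: pd.DataFrame | None = None,
    emotions: Sequence[str] = ("anger", "happy"),
) -> dict[tuple[str, str], dict]:
    """Prototype pools per category x gender.

    quadrant mode: within each quadrant x gender, the ``k`` eligible faces
    with the largest distance from the origin (descending, ties broken by
    face_id).  emotion mode: per gender, the ``k`` faces with the largest
    output probability for each named emotion.  Pools smaller than ``k``
    are returned whole with ``flagged=True``.
    """
    if positions.empty:
        raise ValueError("position table is empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    windows = windows or QuadrantWindows()
    pools: dict[tuple[str, str], dict] = {}
    if mode == "quadrant":
        for q in windows.windows:
            for gender in positions["gender"].unique():
                sub = positions[
                    (positions["quadrant"] == q) & (positions["gender"] == gender)
                ]
                ids, flagged = _topk(sub, "E_hat", k, ascending=False)
                pools[(f"Q{q}", gender)] = {"face_ids": ids, "flagged": flagged}
    elif mode == "emotion":
        if emotion_outputs is None:
            raise ValueError("emotion mode needs emotion_outputs")
        merged = positions.merge(
            emotion_outputs.reset_index(names="face_id"), on="face_id"
        )
        for emo in emotions:
            for gender in merged["gender"].unique():
                sub = merged[merged["gender"] == gender]
                ids, flagged = _topk(sub, emo, k, ascending=False)
                pools[(emo, gender)] = {"face_ids": ids, "flagged": flagged}
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    return pools


def select_origin_bases(positions: pd.DataFrame, n_per_gender: int = 4) -> list[str]:
    """Per gender, the ``n_per_gender`` faces closest to the origin."""
    out: list[str] = []
    for gender in sorted(positions["gender"].unique()):
        sub = positions[positions["gender"] == gender]
        if len(sub) < n_per_gender:
            raise ValueError(f"fewer than {n_per_gender} faces for gender {gender!r}")
        ids, _ = _topk(sub, "E_hat", n_per_gender, ascending=True)
        out += ids
    return out
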
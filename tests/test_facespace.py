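"""Face-space tests: coefficient-table projections, polar geometry,
quadrant windows, and selection against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from facetriad import EMOTIONS_SIX, facespace
from facetriad.facespace import (
    DEFAULT_LOADINGS,
    KnutsonCoefficients,
    QuadrantWindows,
    assign_quadrant,
    polar,
    position_table,
    project,
    select_origin_bases,
    select_prototypes,
)


def one_hot(emotion):
    return {e: float(e == emotion) for e in EMOTIONS_SIX}


class TestProject:
    @pytest.mark.parametrize("emotion", EMOTIONS_SIX)
    def test_one_hot_reproduces_loading_table(self, emotion):
        d, a = project(one_hot(emotion))
        assert (d, a) == DEFAULT_LOADINGS[emotion]

    def test_pure_neutral_origin(self):
        d, a = project({e: 0.0 for e in EMOTIONS_SIX})
        assert (d, a) == (0.0, 0.0)

    def test_neutral_probability_ignored(self):
        withn = dict(one_hot("happy"), neutral=0.7)
        assert project(withn) == project(one_hot("happy"))

    def test_anger_sad_mixture_hand_dot_product(self):
        d, a = project({"anger": 0.5, "sad": 0.5, "disgust": 0, "happy": 0,
                        "fear": 0, "surprise": 0})
        assert d == pytest.approx(0.0)
        assert a == pytest.approx(-0.7)

    def test_missing_emotion_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            project({"anger": 1.0})

    def test_bad_coefficient_table_rejected(self):
        with pytest.raises(ValueError):
            KnutsonCoefficients(dominance={"anger": 1.0}, affiliation={"anger": -1.5})

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 1), min_size=6, max_size=6),
        st.lists(st.floats(0, 1), min_size=6, max_size=6),
        st.floats(0, 1),
    )
    def test_linearity(self, p1, p2, alpha):
        i1 = dict(zip(EMOTIONS_SIX, p1))
        i2 = dict(zip(EMOTIONS_SIX, p2))
        mix = {e: alpha * i1[e] + (1 - alpha) * i2[e] for e in EMOTIONS_SIX}
        d1, a1 = project(i1)
        d2, a2 = project(i2)
        dm, am = project(mix)
        assert dm == pytest.approx(alpha * d1 + (1 - alpha) * d2, abs=1e-9)
        assert am == pytest.approx(alpha * a1 + (1 - alpha) * a2, abs=1e-9)


class TestPolar:
    @pytest.mark.parametrize("d,a,e,theta", [
        (0.0, 1.0, 1.0, 0.0),
        (1.0, 0.0, 1.0, 90.0),
        (0.0, -1.0, 1.0, 180.0),
        (-1.0, 0.0, 1.0, 270.0),
    ])
    def test_axis_cases(self, d, a, e, theta):
        assert polar(d, a) == (pytest.approx(e), pytest.approx(theta))

    def test_one_hot_anger_polar(self):
        d, a = project(one_hot("anger"))
        e, theta = polar(d, a)
        assert e == pytest.approx(np.sqrt(3.25), abs=1e-9)
        assert theta == pytest.approx(np.degrees(np.arctan2(1.0, -1.5)), abs=1e-9)
        assert theta == pytest.approx(146.3099, abs=1e-3)

    def test_origin(self):
        assert polar(0.0, 0.0) == (0.0, 0.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            polar(np.nan, 0.0)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-5, 5), st.floats(-5, 5))
    def test_round_trip(self, d, a):
        e, theta = polar(d, a)
        th = np.deg2rad(theta)
        assert e * np.cos(th) == pytest.approx(a, abs=1e-9)
        assert e * np.sin(th) == pytest.approx(d, abs=1e-9)


class TestQuadrants:
    def test_default_window_cases(self):
        assert assign_quadrant(45.0, 0.5) == "I"
        assert assign_quadrant(45.0, 0.10) == "none"  # fails distance > 0.15
        assert assign_quadrant(45.0, 0.15) == "none"  # boundary not included
        assert assign_quadrant(90.0, 1.0) == "none"  # gap between 80 and 100
        assert assign_quadrant(135.0, 0.3) == "II"
        assert assign_quadrant(225.0, 0.3) == "III"
        assert assign_quadrant(300.0, 0.3) == "IV"

    def test_window_bounds_inclusive(self):
        assert assign_quadrant(10.0, 1.0) == "I"
        assert assign_quadrant(80.0, 1.0) == "I"

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            QuadrantWindows(windows={"III": (190.0, 260.0), "IV": (190.0, 350.0)})

    def test_sign_consistency_with_coordinates(self, rng):
        """Quadrant labels agree with the coordinate-sign oracle."""
        signs = {"I": (1, 1), "II": (1, -1), "III": (-1, -1), "IV": (-1, 1)}
        for _ in range(500):
            d, a = rng.uniform(-2, 2, 2)
            e, theta = polar(d, a)
            q = assign_quadrant(theta, e)
            if q != "none":
                sd, sa = signs[q]
                assert d * sd > 0 and a * sa > 0


def _random_positions(n=500, seed=0):
    rng = np.random.default_rng(seed)
    d = rng.uniform(-2, 2, n)
    a = rng.uniform(-2, 2, n)
    rows = []
    for i in range(n):
        e, theta = polar(d[i], a[i])
        rows.append(
            {
                "face_id": f"f{i:04d}",
                "gender": ["female", "male"][i % 2],
                "D_hat": d[i],
                "A_hat": a[i],
                "E_hat": e,
                "theta_deg": theta,
                "quadrant": assign_quadrant(theta, e),
            }
        )
    return pd.DataFrame(rows)


class TestSelection:
    def test_top1_picks_farther_face(self):
        df = pd.DataFrame(
            {
                "face_id": ["a", "b"],
                "gender": ["female", "female"],
                "E_hat": [0.3, 0.6],
                "theta_deg": [45.0, 45.0],
                "quadrant": ["I", "I"],
            }
        )
        pools = select_prototypes(df, k=1)
        assert pools[("QI", "female")]["face_ids"] == ["b"]

    def test_k_larger_than_pool_flagged(self):
        df = _random_positions(20)
        pools = select_prototypes(df, k=50)
        assert all(info["flagged"] for info in pools.values())

    def test_selection_matches_sort_oracle(self):
        """Top-k selection equals an exhaustive sort on 500 positions."""
        df = _random_positions(500, seed=11)
        pools = select_prototypes(df, k=20)
        for (cat, gender), info in pools.items():
            q = cat[1:]
            sub = df[(df["quadrant"] == q) & (df["gender"] == gender)]
            oracle = sub.sort_values(
                ["E_hat", "face_id"], ascending=[False, True]
            )["face_id"].head(20)
            assert info["face_ids"] == list(oracle)

    def test_origin_bases_match_sort_oracle(self):
        df = _random_positions(100, seed=4)
        bases = select_origin_bases(df, n_per_gender=4)
        for gender in ("female", "male"):
            sub = df[df["gender"] == gender]
            oracle = list(
                sub.sort_values(["E_hat", "face_id"])["face_id"].head(4)
            )
            assert [b for b in bases if b in set(sub["face_id"])] == oracle

    def test_exact_origin_face_selected_first(self):
        df = _random_positions(50, seed=2)
        df.loc[7, ["D_hat", "A_hat", "E_hat", "theta_deg"]] = [0, 0, 0, 0]
        bases = select_origin_bases(df, n_per_gender=1)
        assert df.loc[7, "face_id"] in bases

    def test_insufficient_faces_rejected(self):
        df = _random_positions(4)
        with pytest.raises(ValueError):
            select_origin_bases(df, n_per_gender=10)

    def test_emotion_mode_top_probability(self):
        df = _random_positions(10, seed=3)
        rng = np.random.default_rng(0)
        probs = pd.DataFrame(
            rng.random((10, 2)), columns=["anger", "happy"],
            index=df["face_id"],
        )
        pools = select_prototypes(df, k=2, mode="emotion", emotion_outputs=probs)
        merged = df.merge(probs.reset_index(names="face_id"), on="face_id")
        for emo in ("anger", "happy"):
            for gender in ("female", "male"):
                sub = merged[merged["gender"] == gender]
                oracle = list(
                    sub.sort_values([emo, "face_id"], ascending=[False, True])
                    ["face_id"].head(2)
                )
                assert pools[(emo, gender)]["face_ids"] == oracle


def test_position_table_consistency(rng):
    probs = rng.random((20, 6))
    probs /= probs.sum(1, keepdims=True)
    outputs = pd.DataFrame(probs, columns=list(EMOTIONS_SIX),
                           index=[f"f{i}" for i in range(20)])
    table = position_table(outputs)
    np.testing.assert_allclose(
        table["E_hat"], np.hypot(table["D_hat"], table["A_hat"]), atol=1e-9
    )
    assert table["theta_deg"].between(0, 360, inclusive="left").all()
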
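"""Zone histogramming, dominance rule, weighted score, area categories."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ihcscore import (
    EmptyInputError,
    NoScoreablePixelsError,
    ZoneHistogram,
    assign_grade,
    average_grade,
    dominance_grade,
    score_image,
    stained_area,
    weighted_score,
    zone_histogram,
)
from ihcscore.scoring import round_half_up
from ihcscore.synthetic_ihc import default_image_spec, render


def zone_of(intensity: int) -> str:
    """Independent per-pixel classifier used as the exhaustive oracle."""
    if intensity <= 60:
        return "n3"
    if intensity <= 120:
        return "n2"
    if intensity <= 170:
        return "n1"
    if intensity <= 230:
        return "n0"
    return "n_excluded"


def hist_by_loop(img) -> ZoneHistogram:
    counts = {"n3": 0, "n2": 0, "n1": 0, "n0": 0, "n_excluded": 0}
    for v in np.asarray(img).ravel():
        counts[zone_of(int(v))] += 1
    return ZoneHistogram(**counts)


class TestZoneHistogram:
    def test_printed_boundary_values(self):
        # one pixel at each printed zone edge
        img = np.array([[60, 61, 170, 230, 231]], dtype=np.uint8)
        h = zone_histogram(img)
        assert (h.n3, h.n2, h.n1, h.n0, h.n_excluded) == (1, 1, 1, 1, 1)

    @pytest.mark.parametrize(
        "intensity,zone",
        [(0, "n3"), (60, "n3"), (61, "n2"), (120, "n2"), (121, "n1"),
         (170, "n1"), (171, "n0"), (230, "n0"), (231, "n_excluded"),
         (255, "n_excluded")],
    )
    def test_every_boundary(self, intensity, zone):
        h = zone_histogram(np.full((3, 3), intensity, dtype=np.uint8))
        assert getattr(h, zone) == 9 and h.total == 9

    def test_uniform_image(self):
        h = zone_histogram(np.full((10, 10), 40, dtype=np.uint8))
        assert h.n3 == h.total == 100

    def test_empty_image_rejected(self):
        with pytest.raises(EmptyInputError):
            zone_histogram(np.zeros((0, 0), dtype=np.uint8))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.integers(1, 64), st.integers(1, 64))
    def test_matches_exhaustive_pixel_loop(self, seed, h, w):
        img = np.random.default_rng(seed).integers(0, 256, (h, w), dtype=np.uint8)
        assert zone_histogram(img) == hist_by_loop(img)
        assert zone_histogram(img).total == h * w  # counts conservation


class TestDominance:
    def test_strict_majority_grades_directly(self):
        assert dominance_grade(ZoneHistogram(70, 10, 10, 10, 0)) == 3
        assert dominance_grade(ZoneHistogram(0, 0, 0, 100, 50)) == 0
        assert dominance_grade(ZoneHistogram(0, 10, 80, 10, 0)) == 1

    def test_exactly_66_percent_is_not_dominant(self):
        assert dominance_grade(ZoneHistogram(66, 34, 0, 0, 0)) is None

    def test_all_excluded_raises(self):
        with pytest.raises(NoScoreablePixelsError):
            dominance_grade(ZoneHistogram(0, 0, 0, 0, 100))

    def test_excluded_pixels_not_in_denominator(self):
        # 67 of 100 scoreable, plus excluded bulk: still dominant
        assert dominance_grade(ZoneHistogram(67, 33, 0, 0, 1000)) == 3


class TestWeightedScore:
    def test_single_zone_and_uniform_mixture(self):
        assert weighted_score(ZoneHistogram(0, 50, 0, 0, 7)) == 2.0
        assert weighted_score(ZoneHistogram(25, 25, 25, 25, 0)) == 1.5

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.tuples(*[st.integers(0, 500)] * 4).filter(lambda t: sum(t) > 0),
           st.integers(0, 500))
    def test_matches_direct_formula(self, counts, excl):
        n3, n2, n1, n0 = counts
        h = ZoneHistogram(n3, n2, n1, n0, excl)
        expected = (3 * n3 + 2 * n2 + n1) / (n3 + n2 + n1 + n0)
        assert weighted_score(h) == pytest.approx(expected)
        assert 0.0 <= weighted_score(h) <= 3.0


class TestAssignGrade:
    def test_dominant_zone_wins(self):
        r = assign_grade(ZoneHistogram(70, 10, 10, 10, 0))
        assert r.grade == 3 and r.dominance_applied

    def test_weighted_path_rounds_half_up(self):
        r = assign_grade(ZoneHistogram(25, 25, 25, 25, 0))
        assert (r.grade, r.dominance_applied, r.weighted_score) == (2, False, 1.5)

    def test_dominance_of_light_zone(self):
        r = assign_grade(ZoneHistogram(0, 10, 80, 10, 0))
        assert r.grade == 1 and r.dominance_applied

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 3), st.tuples(*[st.integers(0, 30)] * 3))
    def test_dominance_supremacy(self, zone, others):
        # force one zone strictly above 66% of scoreable pixels
        counts = [0, 0, 0, 0]
        for i, c in zip([z for z in range(4) if z != zone], others):
            counts[i] = c
        counts[zone] = 2 * sum(others) + 1  # > 66% guaranteed
        h = ZoneHistogram(counts[3], counts[2], counts[1], counts[0], 5)
        r = assign_grade(h)
        assert r.grade == zone and r.dominance_applied

    def test_moving_pixel_darker_never_lowers_score(self):
        base = ZoneHistogram(10, 20, 30, 40, 0)
        s0 = weighted_score(base)
        darker = ZoneHistogram(10, 21, 29, 40, 0)  # one pixel zone1 -> zone2
        assert weighted_score(darker) >= s0


class TestStainedArea:
    @pytest.mark.parametrize(
        "stained,category",
        [(5, "negative"), (9, "negative"), (10, "focal"), (19, "focal"),
         (20, "patchy"), (69, "patchy"), (70, "diffused"), (100, "diffused")],
    )
    def test_category_bins(self, stained, category):
        # `stained` of 100 scoreable pixels at intensity 100, rest at 200
        img = np.full(100, 200, dtype=np.uint8)
        img[:stained] = 100
        r = stained_area(img.reshape(10, 10))
        assert r.stained_fraction == pytest.approx(stained / 100)
        assert r.category == category

    def test_uniform_barely_stained_image_is_negative(self):
        r = stained_area(np.full((5, 5), 200, dtype=np.uint8))
        assert r.stained_fraction == 0.0 and r.category == "negative"

    def test_excluded_pixels_ignored(self):
        img = np.array([[100, 240, 240, 240]], dtype=np.uint8)
        assert stained_area(img).stained_fraction == 1.0

    def test_all_excluded_raises(self):
        with pytest.raises(NoScoreablePixelsError):
            stained_area(np.full((4, 4), 255, dtype=np.uint8))


class TestScoreImage:
    def test_pure_white_image_has_no_scoreable_pixels(self):
        with pytest.raises(NoScoreablePixelsError):
            score_image(np.full((8, 8, 3), 255, dtype=np.uint8))

    def test_single_zone_synthetic_image_recovers_grade(self):
        si = render(default_image_spec(2), noise_sd=0, seed=11)
        s = score_image(si.rgb)
        assert s.grade.grade == 2 and s.grade.dominance_applied

    def test_geometric_invariance(self):
        si = render(default_image_spec(1), seed=13)
        base = score_image(si.rgb).grade
        rot = score_image(np.rot90(si.rgb).copy()).grade
        flip = score_image(si.rgb[::-1].copy()).grade
        rng = np.random.default_rng(0)
        flat = si.rgb.reshape(-1, 3).copy()
        rng.shuffle(flat, axis=0)
        shuf = score_image(flat.reshape(si.rgb.shape)).grade
        assert base == rot == flip == shuf


class TestAverageGrade:
    @pytest.mark.parametrize(
        "scores,grade", [([2.0, 2.0], 2), ([1.4, 1.8], 2), ([0.0], 0)]
    )
    def test_mean_then_round_half_up(self, scores, grade):
        r = average_grade(scores)
        assert r.grade == grade and not r.dominance_applied

    def test_empty_list_rejected(self):
        with pytest.raises(EmptyInputError):
            average_grade([])


@pytest.mark.parametrize("x,expected", [(1.5, 2), (2.5, 3), (1.49, 1), (0.5, 1)])
def test_round_half_up(x, expected):
    assert round_half_up(x) == expected
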
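"""Four-tier zone-histogram grading of the pure-DAB channel.

The unmixed DAB channel is an 8-bit image where darker means more
chromogen.  Pixels are binned into four closed intensity zones

=========  ============  =====
zone       intensities   grade
=========  ============  =====
zone 3     0 - 60        3+  (high positive)
zone 2     61 - 120      2+  (positive)
zone 1     121 - 170     1+  (low positive)
zone 0     171 - 230     0   (negative)
excluded   231 - 255     --
=========  ============  =====

The brightest range is excluded because fatty tissue and empty background
in breast sections fall there.  An image where one zone holds strictly more
than 66% of the scoreable (non-excluded) pixels takes that zone's grade
directly; otherwise the grade is the zone-weighted mean intensity score
``(3*n3 + 2*n2 + 1*n1) / (n3+n2+n1+n0)`` rounded half up.

A separate pathologist-style read-out reports the stained area fraction
(any positive-zone pixel counts as stained) in the conventional categories
negative (<10%), focal (10-20%), patchy (20-70%) and diffused (>70%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import EmptyInputError, NoScoreablePixelsError
from . import stain_separation as ss

#: Upper edges of zones 3+, 2+, 1+, 0 and of the scoreable range.
DEFAULT_ZONE_BOUNDS = (60, 120, 170, 230)
DEFAULT_DOMINANCE_THRESHOLD = 0.66
DEFAULT_STAINED_AREA_THRESHOLD = 170

GRADE_LABELS = {0: "0", 1: "1+", 2: "2+", 3: "3+"}

AREA_CATEGORIES = ("negative", "focal", "patchy", "diffused")


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero (1.5 -> 2)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ZoneHistogram:
    """Pixel counts per intensity zone of one DAB channel image."""

    n3: int
    n2: int
    n1: int
    n0: int
    n_excluded: int

    @property
    def total(self) -> int:
        return self.n3 + self.n2 + self.n1 + self.n0 + self.n_excluded

    @property
    def n_scoreable(self) -> int:
        return self.n3 + self.n2 + self.n1 + self.n0

    @property
    def counts(self) -> tuple[int, int, int, int]:
        """(n3, n2, n1, n0) — scoreable zone counts, darkest first."""
        return (self.n3, self.n2, self.n1, self.n0)


@dataclass(frozen=True)
class GradeResult:
    grade: int  # 0..3
    dominance_applied: bool
    weighted_score: float
    zone_fractions: tuple[float, float, float, float]  # of scoreable, (z3,z2,z1,z0)

    @property
    def grade_label(self) -> str:
        return GRADE_LABELS[self.grade]


@dataclass(frozen=True)
class StainedAreaResult:
    stained_fraction: float
    category: str


@dataclass(frozen=True)
class ImageScore:
    """Full per-image scoring record."""

    histogram: ZoneHistogram
    grade: GradeResult
    stained_area: StainedAreaResult


def zone_histogram(dab: np.ndarray, bounds=DEFAULT_ZONE_BOUNDS) -> ZoneHistogram:
    """Bin an 8-bit DAB channel into the four zones plus the excluded range."""
    dab = np.asarray(dab)
    if dab.size == 0:
        raise EmptyInputError("empty image")
    b3, b2, b1, b0 = bounds
    edges = [-0.5, b3 + 0.5, b2 + 0.5, b1 + 0.5, b0 + 0.5, 255.5]
    counts, _ = np.histogram(dab.ravel(), bins=edges)
    n3, n2, n1, n0, n_excluded = (int(c) for c in counts)
    return ZoneHistogram(n3, n2, n1, n0, n_excluded)


def dominance_grade(
    h: ZoneHistogram, threshold: float = DEFAULT_DOMINANCE_THRESHOLD
) -> int | None:
    """Grade directly when one zone holds strictly more than ``threshold``
    of the scoreable pixels; otherwise ``None``."""
    if h.n_scoreable == 0:
        raise NoScoreablePixelsError("all pixels fall in the excluded bright range")
    cutoff = threshold * h.n_scoreable
    for grade, count in zip((3, 2, 1, 0), h.counts):
        if count > cutoff:
            return grade
    return None


def weighted_score(h: ZoneHistogram) -> float:
    """Zone-weighted mean score over non-excluded pixels, in [0, 3]."""
    if h.n_scoreable == 0:
        raise NoScoreablePixelsError("all pixels fall in the excluded bright range")
    return (3 * h.n3 + 2 * h.n2 + 1 * h.n1) / h.n_scoreable


def assign_grade(
    h: ZoneHistogram,
    threshold: float = DEFAULT_DOMINANCE_THRESHOLD,
    rounding=round_half_up,
) -> GradeResult:
    """Dominance rule first; else the weighted score rounded to a grade."""
    dom = dominance_grade(h, threshold)
    score = weighted_score(h)
    fractions = tuple(c / h.n_scoreable for c in h.counts)
    if dom is not None:
        return GradeResult(dom, True, score, fractions)
    return GradeResult(rounding(score), False, score, fractions)


def grade_from_fractions(
    fractions, threshold: float = DEFAULT_DOMINANCE_THRESHOLD, rounding=round_half_up
) -> int:
    """Apply the grading rules to exact zone fractions (z3, z2, z1, z0).

    Used to derive analytic ground-truth grades for synthetic images.
    """
    f3, f2, f1, f0 = fractions
    total = f3 + f2 + f1 + f0
    for grade, f in zip((3, 2, 1, 0), (f3, f2, f1, f0)):
        if f > threshold * total:
            return grade
    return rounding((3 * f3 + 2 * f2 + 1 * f1) / total)


def stained_area(
    dab: np.ndarray,
    stain_threshold: int = DEFAULT_STAINED_AREA_THRESHOLD,
    bounds=DEFAULT_ZONE_BOUNDS,
) -> StainedAreaResult:
    """Stained-area fraction and its pathological category.

    A non-excluded pixel counts as stained when its intensity is at or
    below ``stain_threshold`` (default: any positive-zone pixel).
    """
    dab = np.asarray(dab)
    if dab.size == 0:
        raise EmptyInputError("empty image")
    exclusion_cutoff = bounds[3]
    scoreable = dab.ravel()[dab.ravel() <= exclusion_cutoff]
    if scoreable.size == 0:
        raise NoScoreablePixelsError("all pixels fall in the excluded bright range")
    fraction = float(np.count_nonzero(scoreable <= stain_threshold) / scoreable.size)
    if fraction < 0.10:
        category = "negative"
    elif fraction < 0.20:
        category = "focal"
    elif fraction < 0.70:
        category = "patchy"
    else:
        category = "diffused"
    return StainedAreaResult(fraction, category)


def score_image(
    img: np.ndarray,
    stains: ss.StainMatrix | None = None,
    background=ss.DEFAULT_BACKGROUND,
    bounds=DEFAULT_ZONE_BOUNDS,
    dominance_threshold: float = DEFAULT_DOMINANCE_THRESHOLD,
    stain_threshold: int = DEFAULT_STAINED_AREA_THRESHOLD,
    rounding=round_half_up,
) -> ImageScore:
    """Score one RGB IHC image: unmix DAB, histogram, grade, area category."""
    dab, _ = ss.separate_dab(img, stains, background)
    h = zone_histogram(dab, bounds)
    grade = assign_grade(h, dominance_threshold, rounding)
    area = stained_area(dab, stain_threshold, bounds)
    return ImageScore(h, grade, area)


def average_grade(scores, rounding=round_half_up) -> GradeResult:
    """Aggregate grade over several images of one section.

    Arithmetic mean of the per-image weighted scores, rounded to a grade.
    The dominance rule applies within single images only, never at the
    aggregate level, so ``dominance_applied`` is always False here.
    """
    scores = list(scores)
    if not scores:
        raise EmptyInputError("no scores to average")
    mean = float(np.mean(scores))
    return GradeResult(rounding(mean), False, mean, (float("nan"),) * 4)
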
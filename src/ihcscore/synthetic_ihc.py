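"""Seeded synthetic IHC image generator with analytic ground truth.

Real DAB/hematoxylin slides for this assay are not publicly deposited, so
the test bed is a physics-forward renderer: each image is a mosaic of
rectangular tiles assigned to tissue regions (DAB-stained tumor in a chosen
intensity zone, hematoxylin-dominated nuclei/stroma, and bright fatty
background), per-pixel stain concentrations are drawn uniformly within the
region's range, and RGB values follow Beer-Lambert absorption
``I_ch = background_ch * 10**(-(A @ c)_ch)`` under the configured stain
matrix, with optional additive Gaussian channel noise.

Concentration ranges for a target zone are obtained by inverting the
render equation (``c = -log10(I / 255)``) with a safety margin inside the
zone edges, so the calibration tracks whatever stain matrix is configured.
The ground-truth grade is computed analytically from the realized zone
fractions using the same grading rules the scorer applies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidSpecError
from . import scoring
from .stain_separation import StainMatrix, DEFAULT_BACKGROUND

#: Default additive Gaussian channel noise (8-bit intensity units).
DEFAULT_NOISE_SD = 2.0

#: Safety margin (intensity units) kept inside zone edges when calibrating
#: concentration ranges, absorbing quantization error of the round trip.
ZONE_MARGIN = 5

_ZONE_BY_LABEL = {"3+": 3, "2+": 2, "1+": 1, "0": 0, "background": None}

#: Grade-by-subtype layout of a published 108-case breast-tumor hNIS IHC
#: cohort (counts of 2+/1+/0 per receptor subtype), used as a realistic
#: default cohort design.  No sample scored 3+ in that series.
HNIS_BREAST_COHORT: dict[tuple[str, int], int] = {
    ("ER+/PgR+/HER2-", 2): 14, ("ER+/PgR+/HER2-", 1): 9, ("ER+/PgR+/HER2-", 0): 2,
    ("ER+/PgR+/HER2+", 2): 4, ("ER+/PgR+/HER2+", 1): 5, ("ER+/PgR+/HER2+", 0): 2,
    ("ER-/PgR-/HER2+", 2): 7, ("ER-/PgR-/HER2+", 1): 12, ("ER-/PgR-/HER2+", 0): 8,
    ("ER-/PgR-/HER2-", 2): 8, ("ER-/PgR-/HER2-", 1): 17, ("ER-/PgR-/HER2-", 0): 20,
}


def concentration_range_for_zone(zone: int, margin: int = ZONE_MARGIN) -> tuple[float, float]:
    """DAB concentration interval rendering inside a zone, margin inside edges.

    Inverts ``I = 255 * 10**(-c)``.  For zone 3 the dark edge is kept at
    intensity ``margin`` (not 0) so the optical densities stay finite.
    """
    lo_edge = {3: 0, 2: 61, 1: 121, 0: 171}[zone]
    hi_edge = {3: 60, 2: 120, 1: 170, 0: 230}[zone]
    lo_i = max(lo_edge + margin, margin)
    hi_i = hi_edge - margin
    # darker intensity -> higher concentration
    return (-math.log10(hi_i / 255.0), -math.log10(lo_i / 255.0))


@dataclass(frozen=True)
class RegionSpec:
    """One tissue region of a synthetic image."""

    target_zone: str  # "3+", "2+", "1+", "0" or "background"
    area_fraction: float
    dab_concentration_range: tuple[float, float]
    hematoxylin_concentration_range: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.target_zone not in _ZONE_BY_LABEL:
            raise InvalidSpecError(f"unknown target zone {self.target_zone!r}")
        if not 0.0 <= self.area_fraction <= 1.0:
            raise InvalidSpecError("area_fraction must be in [0, 1]")
        for lo, hi in (self.dab_concentration_range, self.hematoxylin_concentration_range):
            if lo < 0 or hi < lo:
                raise InvalidSpecError("concentration ranges must satisfy 0 <= lo <= hi")

    @classmethod
    def tumor(cls, zone_label: str, area_fraction: float,
              hematoxylin=(0.10, 0.35)) -> "RegionSpec":
        """DAB-stained tumor region calibrated to one intensity zone."""
        zone = _ZONE_BY_LABEL[zone_label]
        if zone is None:
            raise InvalidSpecError("use RegionSpec.background for background regions")
        return cls(zone_label, area_fraction, concentration_range_for_zone(zone), hematoxylin)

    @classmethod
    def stroma(cls, area_fraction: float) -> "RegionSpec":
        """Lightly stained stroma: DAB renders into the negative (0) zone."""
        return cls("0", area_fraction, concentration_range_for_zone(0), (0.05, 0.2))

    @classmethod
    def background(cls, area_fraction: float) -> "RegionSpec":
        """Unstained bright area (fat / empty glass), DAB intensity > 230."""
        return cls("background", area_fraction, (0.0, 0.0), (0.0, 0.0))


@dataclass(frozen=True)
class SyntheticImage:
    rgb: np.ndarray
    ground_truth_grade: int
    ground_truth_zone_fractions: tuple[float, float, float, float]
    seed: int


def default_image_spec(grade: int) -> list[RegionSpec]:
    """Default single-sample layout: 70% tumor in the grade's zone,
    15% light stroma, 15% bright fatty background."""
    label = scoring.GRADE_LABELS[grade]
    if grade == 0:
        return [RegionSpec.tumor("0", 0.70), RegionSpec.stroma(0.15),
                RegionSpec.background(0.15)]
    return [RegionSpec.tumor(label, 0.70), RegionSpec.stroma(0.15),
            RegionSpec.background(0.15)]


def render(
    spec: list[RegionSpec],
    size: tuple[int, int] = (96, 96),
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    stains: StainMatrix | None = None,
    background=DEFAULT_BACKGROUND,
    tile: int = 8,
) -> SyntheticImage:
    """Forward-render a synthetic IHC image from a region specification.

    The image is partitioned into ``tile`` x ``tile`` pixel tiles assigned
    to regions by largest-remainder apportionment and shuffled by the seed,
    giving blocky patches rather than per-pixel salt.
    """
    if noise_sd < 0:
        raise InvalidSpecError("noise_sd must be >= 0")
    total = sum(r.area_fraction for r in spec)
    if abs(total - 1.0) > 1e-9:
        raise InvalidSpecError(f"region area fractions sum to {total}, expected 1")
    if stains is None:
        stains = StainMatrix.preset("hdab")
    h, w = size
    rng = np.random.default_rng(seed)

    ny, nx = math.ceil(h / tile), math.ceil(w / tile)
    n_tiles = ny * nx
    quotas = [r.area_fraction * n_tiles for r in spec]
    counts = [int(math.floor(q)) for q in quotas]
    remainders = np.array([q - c for q, c in zip(quotas, counts)])
    for idx in np.argsort(-remainders)[: n_tiles - sum(counts)]:
        counts[int(idx)] += 1
    assignment = np.repeat(np.arange(len(spec)), counts)
    rng.shuffle(assignment)
    region_of_tile = assignment.reshape(ny, nx)
    region_map = np.repeat(np.repeat(region_of_tile, tile, axis=0), tile, axis=1)[:h, :w]

    dab_c = np.zeros((h, w))
    hema_c = np.zeros((h, w))
    for i, r in enumerate(spec):
        mask = region_map == i
        n = int(mask.sum())
        lo, hi = r.dab_concentration_range
        dab_c[mask] = rng.uniform(lo, hi, n)
        lo, hi = r.hematoxylin_concentration_range
        hema_c[mask] = rng.uniform(lo, hi, n)

    A = stains.matrix
    od = (np.stack([hema_c, dab_c, np.zeros_like(dab_c)], axis=-1)) @ A.T
    rgb = np.asarray(background, dtype=float) * np.power(10.0, -od)
    if noise_sd > 0:
        rgb = rgb + rng.normal(0.0, noise_sd, rgb.shape)
    rgb = np.clip(np.floor(rgb + 0.5), 0, 255).astype(np.uint8)

    # analytic ground truth from the realized region areas
    zone_pixels = {3: 0, 2: 0, 1: 0, 0: 0}
    for i, r in enumerate(spec):
        zone = _ZONE_BY_LABEL[r.target_zone]
        if zone is not None:
            zone_pixels[zone] += int((region_map == i).sum())
    scoreable = sum(zone_pixels.values())
    if scoreable:
        fractions = tuple(zone_pixels[z] / scoreable for z in (3, 2, 1, 0))
        grade = scoring.grade_from_fractions(fractions)
    else:
        fractions = (0.0, 0.0, 0.0, 0.0)
        grade = 0
    return SyntheticImage(rgb, grade, fractions, seed)


@dataclass(frozen=True)
class CohortRecord:
    """Per-sample annotations of a (synthetic or tabulated) cohort."""

    sample_id: str
    er: str  # "positive" / "negative"
    pgr: str
    her2: str
    menopause: str  # "pre" / "post"
    chemo: str  # "pre" / "post"
    manual_grade: int | None
    auto_grade: int | None = None


def _receptors_from_subtype(subtype: str) -> tuple[str, str, str]:
    try:
        er, pgr, her2 = subtype.split("/")
        status = {"+": "positive", "-": "negative"}
        return status[er[-1]], status[pgr[-1]], status[her2[-1]]
    except (ValueError, KeyError):
        raise InvalidSpecError(
            f"subtype {subtype!r} not of the form 'ER+/PgR+/HER2-'"
        ) from None


def tabulate_cohort(
    n_per_cell: dict[tuple[str, int], int] | None = None,
) -> list[CohortRecord]:
    """Expand a (subtype, grade) -> count table into plain cohort records.

    No images are rendered; use this to run summary statistics on a cohort
    known only through its published marginal counts.  Menopause and chemo
    fields are filled with a fixed placeholder ("pre").
    """
    if n_per_cell is None:
        n_per_cell = HNIS_BREAST_COHORT
    if any(v < 0 for v in n_per_cell.values()):
        raise InvalidSpecError("cohort counts must be >= 0")
    out: list[CohortRecord] = []
    i = 0
    for (subtype, grade), count in n_per_cell.items():
        er, pgr, her2 = _receptors_from_subtype(subtype)
        for _ in range(count):
            out.append(CohortRecord(
                sample_id=f"S{i:04d}", er=er, pgr=pgr, her2=her2,
                menopause="pre", chemo="pre", manual_grade=grade,
            ))
            i += 1
    return out


def generate_cohort(
    n_per_cell: dict[tuple[str, int], int] | None = None,
    seed: int = 0,
    size: tuple[int, int] = (96, 96),
    noise_sd: float = DEFAULT_NOISE_SD,
    stains: StainMatrix | None = None,
) -> list[tuple[SyntheticImage, CohortRecord]]:
    """Generate a labelled synthetic cohort.

    ``n_per_cell`` maps ``(subtype, true_grade)`` to a sample count;
    defaults to :data:`HNIS_BREAST_COHORT`.  The manual grade of each
    record is the image's analytic ground truth; ``auto_grade`` is left
    unset for the scorer to fill.  Menopause and chemotherapy labels are
    drawn reproducibly from the seed.
    """
    if n_per_cell is None:
        n_per_cell = HNIS_BREAST_COHORT
    if any(v < 0 for v in n_per_cell.values()):
        raise InvalidSpecError("cohort counts must be >= 0")
    rng = np.random.default_rng(seed)
    out: list[tuple[SyntheticImage, CohortRecord]] = []
    i = 0
    for (subtype, grade), count in n_per_cell.items():
        er, pgr, her2 = _receptors_from_subtype(subtype)
        for _ in range(count):
            img_seed = int(rng.integers(0, 2**31 - 1))
            img = render(default_image_spec(grade), size=size,
                         noise_sd=noise_sd, seed=img_seed, stains=stains)
            rec = CohortRecord(
                sample_id=f"S{i:04d}", er=er, pgr=pgr, her2=her2,
                menopause="pre" if rng.random() < 0.44 else "post",
                chemo="post" if rng.random() < 0.15 else "pre",
                manual_grade=img.ground_truth_grade,
            )
            out.append((img, rec))
            i += 1
    return out
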
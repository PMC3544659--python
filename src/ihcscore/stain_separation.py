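"""Color deconvolution of brightfield IHC images into per-stain channels.

A DAB + hematoxylin stained section photographed under brightfield
transmits light according to Beer-Lambert absorption: per channel,
``I = I0 * 10**(-OD)`` where the optical density ``OD`` is the sum of the
contributions of each stain.  Stacking the per-channel optical densities of
a unit amount of each stain as the columns of a 3x3 matrix ``A`` makes
unmixing a linear problem: per pixel, ``od = A @ c`` where ``c`` holds the
stain concentrations, so ``c = inv(A) @ od`` (Ruifrok-Johnston color
deconvolution).  The recovered DAB concentration plane is re-rendered as an
8-bit grayscale image (0 = darkest, 255 = unstained) which downstream
zone-histogram scoring consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import imageio.v3 as iio

from .exceptions import DegenerateStainsError, EmptyInputError, InvalidBackgroundError

log = logging.getLogger(__name__)

#: Floor applied to intensities before the log transform so a fully black
#: pixel (I = 0) maps to a finite optical density (~2.4) instead of +inf.
#: Applied as max(I, eps): unbiased for every intensity >= 1, so the only
#: error in a render/unmix round trip is 8-bit quantization.
OD_EPSILON = 1.0

#: Default per-channel white level of the brightfield background.
DEFAULT_BACKGROUND = (255.0, 255.0, 255.0)

# Widely published H-DAB optical-density vectors (Ruifrok-derived).
_HEMATOXYLIN_OD = (0.650, 0.704, 0.286)
_DAB_OD = (0.269, 0.568, 0.778)


@dataclass(frozen=True)
class StainMatrix:
    """3x3 stain matrix; columns are unit-norm per-channel OD vectors.

    Column order: stain 1 = hematoxylin, stain 2 = DAB, stain 3 = residual
    (by default the normalized cross product of the first two, spanning
    whatever the two dyes do not).
    """

    matrix: np.ndarray
    stain_names: tuple[str, str, str] = ("hematoxylin", "dab", "residual")

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise DegenerateStainsError(f"stain matrix must be 3x3, got {m.shape}")
        norms = np.linalg.norm(m, axis=0)
        if np.any(norms == 0):
            raise DegenerateStainsError("stain matrix has a zero column")
        m = m / norms
        if np.linalg.cond(m) > 1e8:
            raise DegenerateStainsError("stain matrix is singular or ill-conditioned")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "_inverse", np.linalg.inv(m))

    _inverse: np.ndarray = field(init=False, repr=False, default=None)

    @property
    def inverse(self) -> np.ndarray:
        return self._inverse

    @classmethod
    def from_stains(cls, stain1, stain2, names=("hematoxylin", "dab")) -> "StainMatrix":
        """Build from two stain OD vectors; the residual is their cross product."""
        s1 = np.asarray(stain1, dtype=float)
        s2 = np.asarray(stain2, dtype=float)
        residual = np.cross(s1 / np.linalg.norm(s1), s2 / np.linalg.norm(s2))
        nrm = np.linalg.norm(residual)
        if nrm == 0:
            raise DegenerateStainsError("stain vectors are collinear")
        m = np.column_stack([s1, s2, residual / nrm])
        return cls(m, stain_names=(names[0], names[1], "residual"))

    @classmethod
    def preset(cls, name: str) -> "StainMatrix":
        """Named stain matrix preset.  Currently only ``"hdab"``."""
        if name.lower() != "hdab":
            raise DegenerateStainsError(f"unknown stain matrix preset: {name!r}")
        return cls.from_stains(_HEMATOXYLIN_OD, _DAB_OD)

    @classmethod
    def from_file(cls, path) -> "StainMatrix":
        """Read three whitespace/comma-separated rows of three floats.

        Rows of the file are the channel rows of the matrix; columns are
        stains.  Columns are renormalized automatically.
        """
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip().replace(",", " ")
                if not line:
                    continue
                rows.append([float(tok) for tok in line.split()])
        if len(rows) != 3 or any(len(r) != 3 for r in rows):
            raise DegenerateStainsError(f"stain matrix file {path} must hold 3 rows of 3 floats")
        return cls(np.array(rows, dtype=float))


def _validate_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.size == 0:
        raise EmptyInputError("empty image")
    if img.ndim != 3 or img.shape[2] != 3:
        raise EmptyInputError(f"expected HxWx3 RGB image, got shape {img.shape}")
    return img


def rgb_to_od(img: np.ndarray, background=DEFAULT_BACKGROUND) -> np.ndarray:
    """Convert an 8-bit RGB image to per-channel optical density.

    ``OD_c = -log10(max(I_c, eps) / background_c)`` clamped at zero, with
    ``eps`` = :data:`OD_EPSILON`.
    """
    img = _validate_rgb(img)
    bg = np.asarray(background, dtype=float)
    if bg.shape != (3,) or np.any(bg <= 0) or np.any(bg > 255):
        raise InvalidBackgroundError(f"background must be 3 values in (0, 255], got {background}")
    od = -np.log10(np.maximum(img.astype(float), OD_EPSILON) / bg)
    return np.maximum(od, 0.0)


def deconvolve(od: np.ndarray, stains: StainMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unmix an OD image into three concentration planes (H x W each).

    Negative concentrations (noise below the stain plane) are clamped to 0.
    Plane order follows the stain matrix columns.
    """
    od = np.asarray(od, dtype=float)
    conc = od @ stains.inverse.T
    conc = np.maximum(conc, 0.0)
    return conc[..., 0], conc[..., 1], conc[..., 2]


def concentration_to_intensity(conc: np.ndarray) -> np.ndarray:
    """Render a concentration plane as an 8-bit stain-channel image.

    ``I = clamp(round(255 * 10**(-c)), 0, 255)``, round half away from
    zero; 0 is the darkest shade (most stain), 255 the lightest.
    """
    conc = np.asarray(conc, dtype=float)
    scaled = 255.0 * np.power(10.0, -conc)
    # round half away from zero (values are non-negative here)
    return np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.uint8)


def separate_dab(
    img: np.ndarray,
    stains: StainMatrix | None = None,
    background=DEFAULT_BACKGROUND,
) -> tuple[np.ndarray, np.ndarray]:
    """Full unmixing pipeline: RGB image -> (dab, hematoxylin) 8-bit channels."""
    if stains is None:
        stains = StainMatrix.preset("hdab")
    od = rgb_to_od(img, background)
    hema_c, dab_c, _ = deconvolve(od, stains)
    return concentration_to_intensity(dab_c), concentration_to_intensity(hema_c)


def estimate_background(img: np.ndarray, percentile: float = 99.0) -> np.ndarray:
    """Per-channel background estimate as a high percentile of each channel."""
    img = _validate_rgb(img)
    bg = np.percentile(img.reshape(-1, 3).astype(float), percentile, axis=0)
    return np.maximum(bg, 1.0)


def read_rgb(path) -> np.ndarray:
    """Read an 8-bit RGB image (PNG/TIFF/JPEG); drops alpha with a warning."""
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # plugin backends raise assorted error types
        raise EmptyInputError(f"unreadable image {path}: {exc}") from exc
    if arr.ndim == 2:  # grayscale -> replicate
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim == 3 and arr.shape[2] == 4:
        log.warning("dropping alpha channel of %s", path)
        arr = arr[..., :3]
    arr = _validate_rgb(arr)
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return arr


def write_channel(path, channel: np.ndarray) -> None:
    """Write a per-stain grayscale channel image for visual QC."""
    iio.imwrite(path, np.asarray(channel, dtype=np.uint8))
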
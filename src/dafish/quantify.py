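"""Background-corrected integrated probe intensities and the normalized
inter-homolog difference statistic.

The per-cell statistic is ``d = |I_A - I_B| / (I_A + I_B)`` on
background-corrected integrated intensities: 0 means the two homologous
targets were equally accessible to the probe, 1 means signal was absent on
one homolog.  ``d`` is invariant to any overall intensity scale, which is why
it is comparable across cells, exposures and probes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from matplotlib.path import Path

from .segmentation import Contour

__all__ = [
    "CellMeasurement",
    "BackgroundError",
    "EmptyContourError",
    "contour_mask",
    "estimate_background",
    "integrated_intensity",
    "normalized_difference",
    "measure_cell",
]

#: below this d, homologs are reported as indistinguishable
_EQUAL_TOL = 1e-12


class BackgroundError(ValueError):
    """No usable annulus pixels for background estimation."""


class EmptyContourError(ValueError):
    """Contour encloses no pixel centers."""


@dataclass(frozen=True)
class CellMeasurement:
    """Per-cell, per-locus pair of background-corrected integrated intensities."""

    cell_id: str
    locus_id: str
    intensity_a: float
    intensity_b: float
    normalized_difference: float
    weaker_homolog: str  # "A", "B" or "none"
    homolog_labels: tuple = ("A", "B")
    qc_flags: tuple = ()


def contour_mask(contour: Contour, shape) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the contour."""
    verts = contour.vertices
    rmin = max(int(np.floor(verts[:, 0].min())), 0)
    rmax = min(int(np.ceil(verts[:, 0].max())) + 1, shape[0])
    cmin = max(int(np.floor(verts[:, 1].min())), 0)
    cmax = min(int(np.ceil(verts[:, 1].max())) + 1, shape[1])
    mask = np.zeros(shape, dtype=bool)
    if rmin >= rmax or cmin >= cmax:
        return mask
    rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
    pts = np.column_stack([cc.ravel(), rr.ravel()])  # path is in (x, y) = (col, row)
    path = Path(verts[:, ::-1])
    inside = path.contains_points(pts).reshape(rr.shape)
    mask[rmin:rmax, cmin:cmax] = inside
    return mask


def estimate_background(
    image: np.ndarray,
    contour: Contour,
    annulus_width: int = 5,
    dilation: int = 2,
    exclude: Contour | np.ndarray | None = None,
) -> float:
    """Median pixel value in an annulus outside the dilated contour.

    ``exclude`` (the partner spot's contour, or a boolean mask) removes its
    pixels — after the same dilation — from the annulus; an annulus with no
    remaining pixels raises :class:`BackgroundError`.
    """
    img = np.asarray(image, dtype=float)
    inner = ndi.binary_dilation(contour_mask(contour, img.shape), iterations=dilation)
    ring = ndi.binary_dilation(inner, iterations=annulus_width) & ~inner
    if exclude is not None:
        ex = exclude if isinstance(exclude, np.ndarray) else contour_mask(exclude, img.shape)
        ring &= ~ndi.binary_dilation(ex, iterations=dilation)
    if not ring.any():
        raise BackgroundError("background annulus has no usable pixels")
    return float(np.median(img[ring]))


def integrated_intensity(image: np.ndarray, contour: Contour, background: float) -> float:
    """Sum of ``max(value - background, 0)`` over pixel centers inside the contour.

    Negative background-corrected pixels are clipped at zero before summation
    so noise cannot drive the integral negative.
    """
    img = np.asarray(image, dtype=float)
    mask = contour_mask(contour, img.shape)
    if not mask.any():
        raise EmptyContourError("contour encloses no pixel centers")
    return float(np.clip(img[mask] - background, 0.0, None).sum())


def normalized_difference(intensity_a: float, intensity_b: float) -> float:
    """``|I_A - I_B| / (I_A + I_B)``, in [0, 1]."""
    if intensity_a < 0 or intensity_b < 0:
        raise ValueError("intensities must be >= 0")
    total = intensity_a + intensity_b
    if total <= 0:
        raise ValueError(
            "both integrated intensities are zero: failed hybridization, "
            "normalized difference undefined"
        )
    return abs(intensity_a - intensity_b) / total


def measure_cell(
    probe_image: np.ndarray,
    contour_a: Contour,
    contour_b: Contour,
    cell_id: str = "cell",
    locus_id: str = "locus",
    annulus_width: int = 5,
    dilation: int = 2,
    homolog_labels: tuple = ("A", "B"),
) -> CellMeasurement:
    """Full per-cell measurement from one probe image and two homolog contours."""
    img = np.asarray(probe_image, dtype=float)
    mask_a = contour_mask(contour_a, img.shape)
    mask_b = contour_mask(contour_b, img.shape)
    if (mask_a & mask_b).any():
        raise ValueError("homolog contours overlap; cannot quantify the pair")
    bg_a = estimate_background(img, contour_a, annulus_width, dilation, exclude=mask_b)
    bg_b = estimate_background(img, contour_b, annulus_width, dilation, exclude=mask_a)
    i_a = integrated_intensity(img, contour_a, bg_a)
    i_b = integrated_intensity(img, contour_b, bg_b)
    d = normalized_difference(i_a, i_b)
    weaker = "none" if d <= _EQUAL_TOL else ("A" if i_a < i_b else "B")
    return CellMeasurement(cell_id, locus_id, i_a, i_b, d, weaker, homolog_labels)
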
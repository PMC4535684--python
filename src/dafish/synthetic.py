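"""Synthetic FISH scenes with known ground truth.

Generates 2D two-channel metaphase images and 3D z-stacks containing a pair
of homologous probe signals whose integrated intensities differ by a
controllable normalized difference d = |I_A - I_B| / (I_A + I_B).  Every
rendered scene carries a :class:`GroundTruth` with the noise-free per-homolog
integrated intensities (and, in 3D, axial section spans and voxel counts), so
segmentation and quantification can be validated without real microscope data.

Spots are isotropic Gaussians in-plane (separable Gaussian axially in 3D) on
a constant photon background; noise is Poisson (optionally plus Gaussian read
noise).  The default acquisition geometry mirrors a 3D-SIM reconstruction:
17 optical sections at a 0.13 um axial step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "Distribution",
    "CohortSpec",
    "CohortCell",
    "SceneOverlapError",
    "render_scene_2d",
    "render_scene_3d",
    "generate_cohort",
    "draw_cohort_truths",
    "truth_table",
]

NOISE_MODELS = ("none", "poisson", "poisson_gaussian")

#: numerical floor below which two intensities count as equal
_EQUAL_TOL = 1e-12


class SceneOverlapError(ValueError):
    """Spot centers are too close for paired quantification."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic cell (2D scene or 3D z-stack).

    ``amplitude_a`` / ``amplitude_b`` are the peak photon amplitudes of the
    spots at ``spot_positions[0]`` / ``spot_positions[1]`` (homologs A and B).
    Positions are 0-based ``(row, col)`` or ``(row, col, z)``; a missing z
    defaults to the stack mid-plane.
    """

    image_height: int = 96
    image_width: int = 128
    pixel_size_xy: float = 0.04  # um / pixel
    n_sections: int = 17
    z_step: float = 0.13  # um
    background_level: float = 10.0  # photons / pixel
    spot_sigma_xy: float = 2.0  # pixels
    spot_sigma_z: float = 1.5  # sections
    amplitude_a: float = 200.0  # peak photons, homolog A
    amplitude_b: float = 200.0  # peak photons, homolog B
    spot_positions: tuple = ((48.0, 40.0), (48.0, 88.0))
    noise_model: str = "poisson"
    read_sigma: float = 0.0  # Gaussian read noise, photons (poisson_gaussian)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_a < 0 or self.amplitude_b < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.n_sections < 1:
            raise ValueError("n_sections must be >= 1")
        if self.z_step <= 0 or self.pixel_size_xy <= 0:
            raise ValueError("physical step sizes must be > 0")
        if self.spot_sigma_xy <= 0 or self.spot_sigma_z <= 0:
            raise ValueError("spot sigmas must be > 0")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if len(self.spot_positions) != 2:
            raise ValueError("exactly two spot positions are required")
        for pos in self.spot_positions:
            if not (0 <= pos[0] < self.image_height and 0 <= pos[1] < self.image_width):
                raise ValueError(f"spot center {pos} outside image bounds")
            if len(pos) == 3 and not (0 <= pos[2] < self.n_sections):
                raise ValueError(f"spot z-center {pos} outside the stack")

    @property
    def amplitudes(self) -> tuple:
        return (self.amplitude_a, self.amplitude_b)

    def z_centers(self) -> tuple:
        mid = (self.n_sections - 1) / 2.0
        return tuple(p[2] if len(p) == 3 else mid for p in self.spot_positions)


@dataclass(frozen=True)
class GroundTruth:
    """Noise-free truth for one rendered scene."""

    true_integrated_intensity_a: float
    true_integrated_intensity_b: float
    true_normalized_difference: float
    weaker_homolog: str  # "A", "B" or "none"
    true_section_span_a: int = 0
    true_section_span_b: int = 0
    true_voxel_count_a: int = 0
    true_voxel_count_b: int = 0


def _truth_from_intensities(i_a: float, i_b: float, **kw) -> GroundTruth:
    total = i_a + i_b
    if total <= 0:
        d, weaker = 0.0, "none"
    else:
        d = abs(i_a - i_b) / total
        weaker = "none" if d <= _EQUAL_TOL else ("A" if i_a < i_b else "B")
    return GroundTruth(i_a, i_b, d, weaker, **kw)


def _check_separation(spec: SceneSpec) -> None:
    (r0, c0), (r1, c1) = [p[:2] for p in spec.spot_positions]
    dist = float(np.hypot(r0 - r1, c0 - c1))
    if dist < 6.0 * spec.spot_sigma_xy:
        raise SceneOverlapError(
            f"spot centers {dist:.1f} px apart; < 6 sigma_xy = "
            f"{6 * spec.spot_sigma_xy:.1f} px makes paired quantification unusable"
        )


def _gaussian_2d(shape, center, sigma: float, amplitude: float) -> np.ndarray:
    rr = np.arange(shape[0], dtype=float)[:, None]
    cc = np.arange(shape[1], dtype=float)[None, :]
    return amplitude * np.exp(
        -((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2.0 * sigma**2)
    )


def _apply_noise(noise_free: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.noise_model == "none":
        return noise_free.copy()
    noisy = rng.poisson(noise_free).astype(float)
    if spec.noise_model == "poisson_gaussian" and spec.read_sigma > 0:
        noisy += rng.normal(0.0, spec.read_sigma, size=noisy.shape)
    return noisy


def _counterstain(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Filled-ellipse chromosome pair in the counterstain channel (plumbing only)."""
    rr = np.arange(spec.image_height, dtype=float)[:, None]
    cc = np.arange(spec.image_width, dtype=float)[None, :]
    img = np.full((spec.image_height, spec.image_width), spec.background_level, float)
    semi_r = min(6.0 * spec.spot_sigma_xy, spec.image_height / 3.0)
    semi_c = max(2.0 * spec.spot_sigma_xy, 3.0)
    for pos in spec.spot_positions:
        inside = ((rr - pos[0]) / semi_r) ** 2 + ((cc - pos[1]) / semi_c) ** 2 <= 1.0
        img[inside] += 5.0 * spec.background_level + 10.0
    return _apply_noise(img, spec, rng)


def render_scene_2d(spec: SceneSpec):
    """Render one 2D two-channel scene.

    Returns ``(probe_image, counterstain_image, truth)``.  The truth records
    the noise-free integrated intensity of each spot (pixel sum of the
    rendered Gaussian, excluding background).  Identical spec + seed yields
    bit-identical arrays.
    """
    _check_separation(spec)
    rng = np.random.default_rng(spec.seed)
    shape = (spec.image_height, spec.image_width)
    spots = [
        _gaussian_2d(shape, pos[:2], spec.spot_sigma_xy, amp)
        for pos, amp in zip(spec.spot_positions, spec.amplitudes)
    ]
    noise_free = spec.background_level + spots[0] + spots[1]
    probe = _apply_noise(noise_free, spec, rng)
    counterstain = _counterstain(spec, rng)
    truth = _truth_from_intensities(float(spots[0].sum()), float(spots[1].sum()))
    return probe, counterstain, truth


def _gaussian_3d(spec: SceneSpec, which: int) -> np.ndarray:
    pos = spec.spot_positions[which]
    z0 = spec.z_centers()[which]
    plane = _gaussian_2d(
        (spec.image_height, spec.image_width), pos[:2], spec.spot_sigma_xy, 1.0
    )
    zz = np.arange(spec.n_sections, dtype=float)
    axial = np.exp(-((zz - z0) ** 2) / (2.0 * spec.spot_sigma_z**2))
    return spec.amplitudes[which] * axial[:, None, None] * plane[None, :, :]


def _generator_threshold(background_level: float) -> float:
    """Fixed background-equivalent truth threshold on spot signal above background."""
    return 3.0 * np.sqrt(background_level) if background_level > 0 else 1e-9


def render_scene_3d(spec: SceneSpec):
    """Render one 3D z-stack ``(section, row, col)``.

    Truth axial spans / voxel counts use the generator's own fixed threshold
    (spot signal above ``3 * sqrt(background)``) so they are well defined
    independently of any analysis thresholding.
    """
    _check_separation(spec)
    if spec.spot_sigma_z >= spec.n_sections:
        raise ValueError(
            "spot_sigma_z >= n_sections: axial extent unresolvable on this stack"
        )
    rng = np.random.default_rng(spec.seed)
    spots = [_gaussian_3d(spec, 0), _gaussian_3d(spec, 1)]
    noise_free = spec.background_level + spots[0] + spots[1]
    zstack = _apply_noise(noise_free, spec, rng)

    tau = _generator_threshold(spec.background_level)
    spans, voxels = [], []
    for s in spots:
        mask = s > tau
        voxels.append(int(mask.sum()))
        spans.append(int(mask.any(axis=(1, 2)).sum()))
    truth = _truth_from_intensities(
        float(spots[0].sum()),
        float(spots[1].sum()),
        true_section_span_a=spans[0],
        true_section_span_b=spans[1],
        true_voxel_count_a=voxels[0],
        true_voxel_count_b=voxels[1],
    )
    return zstack, truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class Distribution:
    """Distribution descriptor for per-cell true normalized differences.

    Supported families (all supported on [0, 1]):

    - ``uniform(low, high)``
    - ``constant(value)``
    - ``beta(a, b)``
    """

    family: str
    params: tuple

    def __post_init__(self) -> None:
        fam, p = self.family, self.params
        if fam == "uniform":
            lo, hi = p
            if not (0 <= lo <= hi <= 1):
                raise ValueError("uniform support must lie in [0, 1]")
        elif fam == "constant":
            (v,) = p
            if not 0 <= v <= 1:
                raise ValueError("constant value must lie in [0, 1]")
        elif fam == "beta":
            a, b = p
            if a <= 0 or b <= 0:
                raise ValueError("beta parameters must be > 0")
        else:
            raise ValueError(f"unknown distribution family {fam!r}")

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "uniform":
            return float(rng.uniform(*self.params))
        if self.family == "constant":
            return float(self.params[0])
        return float(rng.beta(*self.params))

    def mean(self) -> float:
        if self.family == "uniform":
            return 0.5 * (self.params[0] + self.params[1])
        if self.family == "constant":
            return float(self.params[0])
        a, b = self.params
        return a / (a + b)

    def variance(self) -> float:
        if self.family == "uniform":
            lo, hi = self.params
            return (hi - lo) ** 2 / 12.0
        if self.family == "constant":
            return 0.0
        a, b = self.params
        return a * b / ((a + b) ** 2 * (a + b + 1))


@dataclass(frozen=True)
class CohortSpec:
    """Cohort of synthetic cells for one locus / treatment condition.

    Defaults emulate an untreated locus with differential accessibility: most
    cells carry a large, directionally consistent inter-homolog asymmetry
    (d ~ U(0.4, 0.9), weaker homolog fixed), the rest a small null asymmetry
    (d ~ U(0, 0.2), weaker side random).
    """

    n_cells: int = 50
    fraction_da_cells: float = 0.85
    da_difference_distribution: Distribution = Distribution("uniform", (0.4, 0.9))
    null_difference_distribution: Distribution = Distribution("uniform", (0.0, 0.2))
    consistent_weaker_homolog: str = "A"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0 <= self.fraction_da_cells <= 1:
            raise ValueError("fraction_da_cells must lie in [0, 1]")
        if self.consistent_weaker_homolog not in ("A", "B"):
            raise ValueError("consistent_weaker_homolog must be 'A' or 'B'")


@dataclass(frozen=True)
class CohortCell:
    """One rendered cohort member."""

    cell_id: str
    spec: SceneSpec
    probe_image: np.ndarray
    counterstain_image: np.ndarray
    truth: GroundTruth
    is_da: bool
    drawn_difference: float


def draw_cohort_truths(cohort: CohortSpec, rng: Optional[np.random.Generator] = None):
    """Draw per-cell (is_da, d, weaker_homolog) triples for a cohort.

    This is the sampling stage of :func:`generate_cohort`, exposed separately
    so statistical properties of the cohort design can be simulated without
    rendering images.
    """
    if rng is None:
        rng = np.random.default_rng(cohort.seed)
    out = []
    for _ in range(cohort.n_cells):
        is_da = bool(rng.random() < cohort.fraction_da_cells)
        dist = (
            cohort.da_difference_distribution
            if is_da
            else cohort.null_difference_distribution
        )
        d = dist.sample(rng)
        weaker = (
            cohort.consistent_weaker_homolog
            if is_da
            else ("A" if rng.random() < 0.5 else "B")
        )
        out.append((is_da, d, weaker))
    return out


def generate_cohort(cohort: CohortSpec, scene_template: SceneSpec):
    """Render a cohort of 2D scenes with known per-cell truth.

    The summed pair amplitude of the template is preserved: for a drawn
    difference d the amplitudes are ``S * (1 +/- d) / 2`` with the dim spot on
    the drawn weaker homolog, so the truth normalized difference equals d.
    """
    rng = np.random.default_rng(cohort.seed)
    draws = draw_cohort_truths(cohort, rng)
    amp_sum = scene_template.amplitude_a + scene_template.amplitude_b
    cells = []
    for i, (is_da, d, weaker) in enumerate(draws):
        bright = amp_sum * (1.0 + d) / 2.0
        dim = amp_sum * (1.0 - d) / 2.0
        amp_a, amp_b = (dim, bright) if weaker == "A" else (bright, dim)
        cell_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(
            scene_template, amplitude_a=amp_a, amplitude_b=amp_b, seed=cell_seed
        )
        probe, counterstain, truth = render_scene_2d(spec)
        cells.append(
            CohortCell(f"cell{i:04d}", spec, probe, counterstain, truth, is_da, d)
        )
    return cells


def truth_table(cells: Sequence[CohortCell], locus_id: str = "locus"):
    """Cohort truths as a tidy table (one row per cell)."""
    import pandas as pd

    rows = []
    for c in cells:
        t = c.truth
        rows.append(
            {
                "cell_id": c.cell_id,
                "locus_id": locus_id,
                "I_A": t.true_integrated_intensity_a,
                "I_B": t.true_integrated_intensity_b,
                "d_true": t.true_normalized_difference,
                "weaker": t.weaker_homolog,
                "span_A": t.true_section_span_a,
                "span_B": t.true_section_span_b,
                "vox_A": t.true_voxel_count_a,
                "vox_B": t.true_voxel_count_b,
            }
        )
    return pd.DataFrame(rows)
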
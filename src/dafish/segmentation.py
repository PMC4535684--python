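"""Gradient-vector-flow (GVF) active-contour delineation of probe signals.

The probe boundary is found by (1) computing an edge map (gradient magnitude
of the Gaussian-smoothed image, optionally binarized), (2) diffusing its
gradient into a GVF field, whose long capture range lets a contour initialized
well outside a spot find the edge, and (3) evolving a closed snake under the
usual tension/rigidity internal forces with the GVF field as external force.

All coordinates are 0-based ``(row, col)``; the GVF components follow the
image-analysis convention ``u`` = x (column) and ``v`` = y (row).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from scipy.linalg import circulant
from shapely.geometry import Polygon

__all__ = [
    "EdgeMap",
    "GVFField",
    "SnakeParams",
    "Contour",
    "PeakDetectionError",
    "DegenerateContourError",
    "compute_edge_map",
    "compute_gvf",
    "detect_probe_peaks",
    "initialize_contour",
    "evolve_snake",
]


class PeakDetectionError(ValueError):
    """Fewer probe signals than expected — hybridization failure for the cell."""


class DegenerateContourError(ValueError):
    """Snake self-intersected: degenerate segmentation, cell excluded."""


@dataclass(frozen=True)
class EdgeMap:
    """Non-negative edge-strength map, normalized to [0, 1]."""

    values: np.ndarray
    smoothing_sigma: float
    binarize_fraction: float = 0.0


@dataclass(frozen=True)
class GVFField:
    """Converged (or truncated) gradient vector flow field."""

    u: np.ndarray  # x (column) component
    v: np.ndarray  # y (row) component
    mu: float
    n_iterations: int
    final_residual: float
    converged: bool


@dataclass(frozen=True)
class SnakeParams:
    """Active-contour parameters (tension alpha, rigidity beta, step gamma,
    external-force weight kappa)."""

    alpha: float = 0.1
    beta: float = 0.1
    gamma: float = 1.0
    kappa: float = 2.0
    max_iterations: int = 500
    convergence_tol: float = 0.02  # mean vertex displacement, pixels

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.kappa) < 0:
            raise ValueError("snake weights must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


@dataclass(frozen=True)
class Contour:
    """Closed polygonal boundary in continuous (row, col) pixel coordinates."""

    vertices: np.ndarray
    closed: bool = True
    converged: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 8:
            raise ValueError("a contour needs >= 8 (row, col) vertices")
        object.__setattr__(self, "vertices", v)

    def is_simple(self) -> bool:
        return Polygon(self.vertices).is_valid

    def area(self) -> float:
        r, c = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))

    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)


def compute_edge_map(
    image: np.ndarray, smoothing_sigma: float = 2.0, binarize_fraction: float = 0.0
) -> EdgeMap:
    """Edge map: gradient magnitude of the Gaussian-smoothed image.

    With ``binarize_fraction > 0`` the magnitude is thresholded at that
    fraction of its maximum, yielding the binary variant.  The result is
    normalized to [0, 1]; a constant image gives an all-zero (valid) map.
    """
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")
    if np.any(img < 0):
        raise ValueError("image must be non-negative")
    sm = ndi.gaussian_filter(img, smoothing_sigma, mode="nearest")
    gr, gc = np.gradient(sm)
    mag = np.hypot(gr, gc)
    mx = float(mag.max())
    if binarize_fraction > 0 and mx > 0:
        mag = (mag >= binarize_fraction * mx).astype(float)
        mx = 1.0
    values = mag / mx if mx > 0 else mag
    return EdgeMap(values, smoothing_sigma, binarize_fraction)


def compute_gvf(
    edge_map,
    mu: float = 0.1,
    max_iterations: int = 500,
    tolerance: float = 1e-4,
    gamma: float | None = None,
) -> GVFField:
    """Diffuse the edge-map gradient into a GVF field.

    Iterates the explicit diffusion update
    ``u <- u + gamma * [mu * lap(u) - (u - f_x) * (f_x^2 + f_y^2)]`` (and v
    analogously) with replicate-edge boundaries until the RMS of the
    Euler-equation residual falls below ``tolerance``.  The default time step
    respects both the diffusion stability bound ``gamma <= 1/(4 mu)`` on a
    unit grid and the data-term decay bound.
    """
    if mu <= 0:
        raise ValueError("mu must be > 0")
    f = edge_map.values if isinstance(edge_map, EdgeMap) else np.asarray(edge_map, float)
    fr, fc = np.gradient(f)
    fx, fy = fc, fr
    b = fx**2 + fy**2
    if gamma is None:
        # strictly inside the explicit-scheme stability region: the update
        # factor 1 - gamma*(8*mu + b) then stays in (-1, 1] everywhere
        gamma = 1.0 / (4.0 * mu + float(b.max()))
    u, v = fx.copy(), fy.copy()
    residual = 0.0
    converged = False
    n_it = 0
    with np.errstate(over="ignore", invalid="ignore"):
        for n_it in range(1, max_iterations + 1):
            ru = mu * ndi.laplace(u, mode="nearest") - (u - fx) * b
            rv = mu * ndi.laplace(v, mode="nearest") - (v - fy) * b
            u = u + gamma * ru
            v = v + gamma * rv
            if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
                raise FloatingPointError(
                    "GVF iteration diverged: time step too large for given mu"
                )
            residual = float(np.sqrt(np.mean(ru**2 + rv**2)))
            if residual < tolerance:
                converged = True
                break
    return GVFField(u, v, mu, n_it, residual, converged)


def detect_probe_peaks(
    probe_image: np.ndarray,
    expected_count: int,
    smoothing_sigma: float = 2.0,
    min_separation: float | None = None,
):
    """Locate probe-signal peaks: smoothed local maxima above background.

    Candidates are ranked by height (ties broken by lexicographic (row, col)
    order) and kept greedily subject to a minimum mutual distance.  Raises
    :class:`PeakDetectionError` when fewer than ``expected_count`` maxima rise
    above the background — a failed hybridization for that cell.
    """
    if expected_count < 1:
        raise ValueError("expected_count must be >= 1")
    if min_separation is None:
        min_separation = 4.0 * smoothing_sigma
    sm = ndi.gaussian_filter(np.asarray(probe_image, float), smoothing_sigma, mode="nearest")
    bg = float(np.median(sm))
    mad = float(np.median(np.abs(sm - bg)))
    threshold = bg + 6.0 * 1.4826 * mad
    local_max = (sm == ndi.maximum_filter(sm, size=3, mode="nearest")) & (sm > threshold)
    # replicate-edge smoothing under-averages the border; a real spot center
    # that close to the frame edge could not be quantified anyway
    margin = max(int(np.ceil(2.0 * smoothing_sigma)), 1)
    local_max[:margin, :] = local_max[-margin:, :] = False
    local_max[:, :margin] = local_max[:, -margin:] = False
    coords = np.argwhere(local_max)
    if coords.size == 0:
        raise PeakDetectionError("no probe signal above background")
    order = sorted(
        range(len(coords)),
        key=lambda i: (-sm[coords[i, 0], coords[i, 1]], coords[i, 0], coords[i, 1]),
    )
    kept: list[tuple[int, int]] = []
    for i in order:
        r, c = int(coords[i, 0]), int(coords[i, 1])
        if all(np.hypot(r - kr, c - kc) >= min_separation for kr, kc in kept):
            kept.append((r, c))
        if len(kept) == expected_count:
            return kept
    raise PeakDetectionError(
        f"found {len(kept)} probe signals, expected {expected_count}"
    )


def initialize_contour(center, radius: float, n_vertices: int = 64) -> Contour:
    """Regular polygon approximating a circle about ``center``."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if n_vertices < 8:
        raise ValueError("n_vertices must be >= 8")
    t = 2.0 * np.pi * np.arange(n_vertices) / n_vertices
    verts = np.column_stack(
        [center[0] + radius * np.sin(t), center[1] + radius * np.cos(t)]
    )
    return Contour(verts)


def _resample_closed(vertices: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polygon to n vertices at uniform arc length."""
    pts = np.vstack([vertices, vertices[:1]])
    seg = np.hypot(np.diff(pts[:, 0]), np.diff(pts[:, 1]))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        return vertices.copy()
    targets = total * np.arange(n) / n
    return np.column_stack(
        [np.interp(targets, s, pts[:, 0]), np.interp(targets, s, pts[:, 1])]
    )


def _internal_matrix(n: int, params: SnakeParams) -> np.ndarray:
    k2 = np.zeros(n)
    k2[[0, 1, -1]] = [2.0, -1.0, -1.0]
    k4 = np.zeros(n)
    k4[[0, 1, 2, -2, -1]] = [6.0, -4.0, 1.0, 1.0, -4.0]
    a = params.alpha * circulant(k2) + params.beta * circulant(k4)
    return np.linalg.inv(np.eye(n) + params.gamma * a)


def evolve_snake(init: Contour, gvf: GVFField, params: SnakeParams = SnakeParams()) -> Contour:
    """Evolve a closed snake to equilibrium in a GVF field.

    Semi-implicit step: the pentadiagonal (circulant) internal-energy system
    is solved exactly each iteration, with the external force
    ``kappa * (u, v)`` sampled by bilinear interpolation; vertices are
    re-sampled to uniform arc length each iteration.  Stops when the mean
    vertex displacement drops below ``convergence_tol`` (else returns the
    last contour flagged unconverged).  A self-intersecting result raises
    :class:`DegenerateContourError`.
    """
    x = init.vertices.copy()
    n = len(x)
    solve = _internal_matrix(n, params)
    converged = False
    for _ in range(params.max_iterations):
        coords = x.T  # (2, n): rows then cols
        f_col = ndi.map_coordinates(gvf.u, coords, order=1, mode="nearest")
        f_row = ndi.map_coordinates(gvf.v, coords, order=1, mode="nearest")
        force = params.kappa * np.column_stack([f_row, f_col])
        x_new = solve @ (x + params.gamma * force)
        disp = float(np.mean(np.hypot(*(x_new - x).T)))
        x = _resample_closed(x_new, n)
        if disp < params.convergence_tol:
            converged = True
            break
    contour = Contour(x, closed=True, converged=converged)
    if not contour.is_simple():
        raise DegenerateContourError("snake self-intersected on output")
    return contour
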
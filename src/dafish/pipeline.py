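"""End-to-end pipeline: simulate -> detect/segment -> quantify -> call DA.

Every stage is deterministic given the seeds in the configuration; any
per-cell failure (hybridization failure, degenerate segmentation, unusable
background) is recorded once in the QC log with a reason code and the locus
statistics are computed on the surviving cells.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as dio
from .quantify import BackgroundError, CellMeasurement, measure_cell
from .segmentation import (
    Contour,
    DegenerateContourError,
    PeakDetectionError,
    SnakeParams,
    compute_edge_map,
    compute_gvf,
    detect_probe_peaks,
    evolve_snake,
    initialize_contour,
)
from .stats import DAConfig, LocusDAResult, TreatmentComparison, compare_pre_post, summarize_locus
from .synthetic import CohortCell, CohortSpec, Distribution, SceneSpec, generate_cohort, truth_table

__all__ = [
    "SegmentationConfig",
    "QuantConfig",
    "RunConfig",
    "CellQCError",
    "PipelineResult",
    "segment_cell",
    "process_cell",
    "analyze_cohort",
    "run_pipeline",
    "config_to_json",
    "config_from_json",
]


class CellQCError(Exception):
    """A cell failed quality control; carries a machine-readable reason code."""

    def __init__(self, reason: str, message: str):
        super().__init__(message)
        self.reason = reason


@dataclass(frozen=True)
class SegmentationConfig:
    """Segmentation parameters, expressed relative to the expected spot sigma.

    The edge-map smoothing default (2.3 x spot sigma) places the edge-map
    gradient ridge slightly outside the radius enclosing ~95 % of a Gaussian
    spot's integrated intensity; the snake's tension pulls it a few percent
    back inside the ridge, so the converged contour delineates that
    photometric boundary.
    """

    smoothing_sigma_factor: float = 2.3
    binarize_fraction: float = 0.0  # > 0 switches to the binary edge-map variant
    gvf_mu: float = 0.1
    gvf_max_iterations: int = 500
    gvf_tolerance: float = 1e-4
    snake: SnakeParams = field(default_factory=SnakeParams)
    init_radius_factor: float = 3.0
    n_vertices: int = 64
    min_separation_factor: float = 6.0  # for peak detection, x spot sigma


@dataclass(frozen=True)
class QuantConfig:
    annulus_width: int = 5
    dilation: int = 2


@dataclass(frozen=True)
class RunConfig:
    """Full, serializable description of one reproducible run."""

    locus_id: str = "locus"
    scene: SceneSpec = field(default_factory=SceneSpec)
    pre: CohortSpec = field(default_factory=CohortSpec)
    post: Optional[CohortSpec] = field(
        default_factory=lambda: CohortSpec(fraction_da_cells=0.15, seed=1)
    )
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    quantification: QuantConfig = field(default_factory=QuantConfig)
    da: DAConfig = field(default_factory=DAConfig)


def segment_cell(
    probe_image: np.ndarray,
    spot_sigma: float,
    seg: SegmentationConfig = SegmentationConfig(),
    expected_positions: Optional[Sequence] = None,
):
    """Detect both homolog signals and return their contours ``(A, B)``.

    With ``expected_positions`` the detected peaks are assigned to homologs by
    proximity to the stated (row, col) centers; otherwise homolog A is the
    left-most peak (column, then row order).
    """
    peaks = detect_probe_peaks(
        probe_image,
        expected_count=2,
        smoothing_sigma=spot_sigma,
        min_separation=seg.min_separation_factor * spot_sigma,
    )
    if expected_positions is not None:
        ref = np.asarray([p[:2] for p in expected_positions], dtype=float)
        dists = [
            [float(np.hypot(p[0] - q[0], p[1] - q[1])) for q in ref] for p in peaks
        ]
        if (dists[0][0] <= dists[0][1]) == (dists[1][0] <= dists[1][1]):
            raise CellQCError("peak_assignment", "peaks could not be paired to homologs")
        ordered = peaks if dists[0][0] <= dists[0][1] else [peaks[1], peaks[0]]
    else:
        ordered = sorted(peaks, key=lambda p: (p[1], p[0]))
    edge = compute_edge_map(
        probe_image, seg.smoothing_sigma_factor * spot_sigma, seg.binarize_fraction
    )
    gvf = compute_gvf(edge, seg.gvf_mu, seg.gvf_max_iterations, seg.gvf_tolerance)
    contours = []
    for peak in ordered:
        init = initialize_contour(peak, seg.init_radius_factor * spot_sigma, seg.n_vertices)
        contours.append(evolve_snake(init, gvf, seg.snake))
    return tuple(contours)


def process_cell(
    probe_image: np.ndarray,
    spot_sigma: float,
    seg: SegmentationConfig = SegmentationConfig(),
    quant: QuantConfig = QuantConfig(),
    cell_id: str = "cell",
    locus_id: str = "locus",
    expected_positions: Optional[Sequence] = None,
) -> CellMeasurement:
    """Segment and quantify one cell; raises :class:`CellQCError` on failure."""
    try:
        contour_a, contour_b = segment_cell(probe_image, spot_sigma, seg, expected_positions)
        return measure_cell(
            probe_image,
            contour_a,
            contour_b,
            cell_id=cell_id,
            locus_id=locus_id,
            annulus_width=quant.annulus_width,
            dilation=quant.dilation,
        )
    except PeakDetectionError as exc:
        raise CellQCError("peak_detection", str(exc)) from exc
    except DegenerateContourError as exc:
        raise CellQCError("degenerate_contour", str(exc)) from exc
    except BackgroundError as exc:
        raise CellQCError("background", str(exc)) from exc
    except ValueError as exc:
        raise CellQCError("quantification", str(exc)) from exc


def analyze_cohort(
    cells: Sequence[CohortCell],
    seg: SegmentationConfig = SegmentationConfig(),
    quant: QuantConfig = QuantConfig(),
    locus_id: str = "locus",
):
    """Run segmentation + quantification on a rendered cohort.

    Returns ``(measurements, qc_log)``; every excluded cell appears exactly
    once in the QC log with its reason code.
    """
    measurements, qc_log = [], []
    for cell in cells:
        try:
            measurements.append(
                process_cell(
                    cell.probe_image,
                    cell.spec.spot_sigma_xy,
                    seg,
                    quant,
                    cell_id=cell.cell_id,
                    locus_id=locus_id,
                    expected_positions=cell.spec.spot_positions,
                )
            )
        except CellQCError as exc:
            qc_log.append(
                {"cell_id": cell.cell_id, "reason": exc.reason, "detail": str(exc)}
            )
    return measurements, qc_log


@dataclass(frozen=True)
class PipelineResult:
    measurements_pre: list
    measurements_post: Optional[list]
    locus_pre: Optional[LocusDAResult]
    locus_post: Optional[LocusDAResult]
    comparison: Optional[TreatmentComparison]
    qc_log: list


def _locus_row(tag: str, res: Optional[LocusDAResult]) -> dict:
    if res is None:
        return {}
    return {
        f"n_{tag}": res.n_cells,
        f"n_da_{tag}": res.n_da_cells,
        f"frac_{tag}": res.da_fraction,
        f"consistent_{tag}": res.consistent_weaker_homolog,
        f"z_{tag}": res.z_vs_null,
        f"p_{tag}": res.p_value,
        f"call_{tag}": res.da_call,
    }


def run_pipeline(config: RunConfig, outdir=None) -> PipelineResult:
    """Simulate the configured cohorts, analyze them and call DA.

    When ``outdir`` is given, all intermediate tables (truth, contoured
    measurements, QC log, locus results), the config and a plain-text report
    are persisted there; identical config implies byte-identical outputs.
    """
    cells_pre = generate_cohort(config.pre, config.scene)
    meas_pre, qc_pre = analyze_cohort(
        cells_pre, config.segmentation, config.quantification, config.locus_id
    )
    qc_log = [dict(entry, cohort="pre") for entry in qc_pre]

    meas_post, cells_post = None, None
    if config.post is not None:
        cells_post = generate_cohort(config.post, config.scene)
        meas_post, qc_post = analyze_cohort(
            cells_post, config.segmentation, config.quantification, config.locus_id
        )
        qc_log += [dict(entry, cohort="post") for entry in qc_post]

    locus_pre = locus_post = comparison = None
    if meas_pre:
        locus_pre = summarize_locus(meas_pre, config.da, config.locus_id)
    if meas_post:
        locus_post = summarize_locus(meas_post, config.da, config.locus_id)
    if (
        meas_pre
        and meas_post
        and len(meas_pre) >= config.da.min_cells
        and len(meas_post) >= config.da.min_cells
    ):
        comparison = compare_pre_post(meas_pre, meas_post, config.da, config.locus_id)

    result = PipelineResult(meas_pre, meas_post, locus_pre, locus_post, comparison, qc_log)
    if outdir is not None:
        _persist(config, result, cells_pre, cells_post, Path(outdir))
    return result


def _persist(config, result, cells_pre, cells_post, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(config_to_json(config))
    dio.write_table(outdir / "truth_pre.tsv", truth_table(cells_pre, config.locus_id))
    dio.write_table(
        outdir / "measurements_pre.tsv", dio.measurements_to_table(result.measurements_pre)
    )
    if cells_post is not None:
        dio.write_table(outdir / "truth_post.tsv", truth_table(cells_post, config.locus_id))
        dio.write_table(
            outdir / "measurements_post.tsv",
            dio.measurements_to_table(result.measurements_post),
        )
    qc = pd.DataFrame(result.qc_log, columns=["cell_id", "reason", "detail", "cohort"])
    dio.write_table(outdir / "qc_log.tsv", qc)

    row = {"locus_id": config.locus_id}
    row.update(_locus_row("pre", result.locus_pre))
    row.update(_locus_row("post", result.locus_post))
    if result.comparison is not None:
        c = result.comparison
        row.update(
            z_pre_post=c.z_pre_post,
            p_pre_post=c.p_pre_post,
            significant_reduction=c.significant_reduction,
            delta_mu_pre=c.delta_mu_pre,
            delta_mu_post=c.delta_mu_post,
            t=c.t_statistic,
            p_t=c.t_p_value,
        )
    dio.write_table(outdir / "locus_results.tsv", pd.DataFrame([row]))
    (outdir / "report.txt").write_text(_report_text(config, result))


def _report_text(config: RunConfig, result: PipelineResult) -> str:
    lines = [f"DA pipeline report — locus {config.locus_id}", ""]
    if not result.measurements_pre:
        lines.append("WARNING: all pre-treatment cells failed QC; no locus statistics.")
    for tag, res in (("pre", result.locus_pre), ("post", result.locus_post)):
        if res is None:
            continue
        call = "underpowered" if res.da_call is None else ("DA" if res.da_call else "no DA")
        lines.append(
            f"{tag}: {res.n_da_cells}/{res.n_cells} cells flagged "
            f"({100 * res.da_fraction:.1f} %), weaker homolog {res.consistent_weaker_homolog}, "
            f"z = {res.z_vs_null:.2f}, p = {res.p_value:.3g} -> {call}"
        )
    if result.comparison is not None:
        c = result.comparison
        lines.append(
            f"pre vs post: z = {c.z_pre_post:.2f} "
            f"({'significant' if c.significant_reduction else 'not significant'} reduction), "
            f"delta_mu {c.delta_mu_pre:.3f} -> {c.delta_mu_post:.3f}, "
            f"Welch t = {c.t_statistic:.2f}, p = {c.t_p_value:.3g}"
        )
    if result.qc_log:
        lines.append("")
        lines.append("QC exclusions:")
        for entry in result.qc_log:
            lines.append(f"  {entry['cohort']} {entry['cell_id']}: {entry['reason']}")
    lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# configuration (de)serialization


def config_to_json(config: RunConfig) -> str:
    return json.dumps(dataclasses.asdict(config), indent=2, sort_keys=True)


def _distribution(d: dict) -> Distribution:
    return Distribution(d["family"], tuple(d["params"]))


def _cohort(d: Optional[dict]) -> Optional[CohortSpec]:
    if d is None:
        return None
    d = dict(d)
    d["da_difference_distribution"] = _distribution(d["da_difference_distribution"])
    d["null_difference_distribution"] = _distribution(d["null_difference_distribution"])
    return CohortSpec(**d)


def config_from_json(text: str) -> RunConfig:
    raw = json.loads(text)
    scene = dict(raw["scene"])
    scene["spot_positions"] = tuple(tuple(p) for p in scene["spot_positions"])
    seg = dict(raw["segmentation"])
    seg["snake"] = SnakeParams(**seg["snake"])
    return RunConfig(
        locus_id=raw["locus_id"],
        scene=SceneSpec(**scene),
        pre=_cohort(raw["pre"]),
        post=_cohort(raw.get("post")),
        segmentation=SegmentationConfig(**seg),
        quantification=QuantConfig(**raw["quantification"]),
        da=DAConfig(**raw["da"]),
    )
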
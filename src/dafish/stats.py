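"""Locus-level differential-accessibility (DA) calling and the statistical
tests used to compare treatment cohorts.

A locus is called DA when at least two-thirds of scored metaphase cells show a
per-cell normalized difference above threshold, the weaker homolog is
directionally consistent across flagged cells, and the flagged fraction is
significantly above the 50 % null by a two-proportion z-test.  Treatment
effects (e.g. topoisomerase-II-alpha inhibition) are assessed by the same
z-test on pre- vs post-treatment DA fractions (reduction significant at
z < -2.0) and a two-tailed Welch t-test on the per-cell differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .quantify import CellMeasurement

__all__ = [
    "DAConfig",
    "LocusDAResult",
    "TreatmentComparison",
    "TwoProportionResult",
    "score_cell_da",
    "summarize_locus",
    "two_proportion_z",
    "compare_pre_post",
    "welch_t_two_tailed",
    "one_way_anova",
    "pearson_r",
]


@dataclass(frozen=True)
class DAConfig:
    """Thresholds for DA scoring and calling.

    ``per_cell_threshold`` 0.3 separates the normalized-difference regime of
    DA loci (medians ~0.5-1) from treated / equal-accessibility loci
    (medians ~0.1-0.3).  ``da_fraction_threshold`` is the two-thirds-of-cells
    criterion, compared inclusively.
    """

    per_cell_threshold: float = 0.3
    min_cells: int = 10
    da_fraction_threshold: float = 2.0 / 3.0
    consistency_fraction: float = 0.75
    alpha: float = 0.05
    null_proportion: float = 0.5
    reduction_z_threshold: float = -2.0
    bonferroni_m: int = 1  # >1 applies Bonferroni to the locus alpha; off by default


class TwoProportionResult(NamedTuple):
    z: float
    p_value: float
    degenerate: bool


@dataclass(frozen=True)
class LocusDAResult:
    locus_id: str
    n_cells: int
    n_da_cells: int
    da_fraction: float
    consistent_weaker_homolog: str  # "A", "B" or "mixed"
    z_vs_null: float
    p_value: float
    da_call: Optional[bool]  # None when underpowered (n below floor)
    underpowered: bool = False


@dataclass(frozen=True)
class TreatmentComparison:
    locus_id: str
    pre: LocusDAResult
    post: LocusDAResult
    z_pre_post: float
    p_pre_post: float
    significant_reduction: bool
    delta_mu_pre: float
    delta_mu_post: float
    t_statistic: float
    t_df: float
    t_p_value: float


def score_cell_da(measurement: CellMeasurement, per_cell_threshold: float = 0.3):
    """Flag a cell as showing DA (inclusive threshold) and report the weaker homolog."""
    flagged = measurement.normalized_difference >= per_cell_threshold
    return flagged, measurement.weaker_homolog


def two_proportion_z(k1, n1, k2, n2) -> TwoProportionResult:
    """Pooled two-proportion z-test, two-sided.

    ``z = (k1/n1 - k2/n2) / sqrt(p(1-p)(1/n1 + 1/n2))`` with the pooled
    estimate ``p = (k1+k2)/(n1+n2)``.  A degenerate pool (p in {0, 1}) carries
    no evidence either way and returns z = 0, flagged.  Counts may be
    non-integer (e.g. a fractional pseudo-count null arm).
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise ValueError("cohort sizes must be > 0")
        if not 0 <= k <= n:
            raise ValueError("counts must satisfy 0 <= k <= n")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled <= 0.0 or pooled >= 1.0:
        return TwoProportionResult(0.0, 1.0, True)
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (k1 / n1 - k2 / n2) / se
    p = 2.0 * sps.norm.sf(abs(z))
    return TwoProportionResult(float(z), float(p), False)


def summarize_locus(
    cells: Sequence[CellMeasurement],
    config: DAConfig = DAConfig(),
    locus_id: Optional[str] = None,
) -> LocusDAResult:
    """Aggregate per-cell measurements into a locus-level DA result.

    The flagged fraction is tested against a 0.5 null proportion using an
    equal-size pseudo-cohort in the two-proportion z-test.  Directional
    consistency requires one homolog to be the weaker one in more than
    ``consistency_fraction`` of flagged cells; otherwise the locus is
    "mixed" and cannot be called DA.  Cohorts below ``min_cells`` are marked
    underpowered and the call is withheld (``da_call=None``).
    """
    if not cells:
        raise ValueError("no cells to summarize")
    if locus_id is None:
        locus_id = cells[0].locus_id
    n = len(cells)
    flags_weakers = [score_cell_da(m, config.per_cell_threshold) for m in cells]
    k = sum(f for f, _ in flags_weakers)
    da_fraction = k / n

    flagged_sides = [w for f, w in flags_weakers if f and w in ("A", "B")]
    consistent = "mixed"
    if flagged_sides:
        n_a = flagged_sides.count("A")
        frac_a = n_a / len(flagged_sides)
        if frac_a > config.consistency_fraction:
            consistent = "A"
        elif 1.0 - frac_a > config.consistency_fraction:
            consistent = "B"

    z, p, _ = two_proportion_z(k, n, config.null_proportion * n, n)
    underpowered = n < config.min_cells
    alpha = config.alpha / max(config.bonferroni_m, 1)
    if underpowered:
        call: Optional[bool] = None
    else:
        call = (
            da_fraction >= config.da_fraction_threshold - 1e-12
            and p < alpha
            and consistent in ("A", "B")
        )
    return LocusDAResult(
        locus_id, n, int(k), da_fraction, consistent, z, p, call, underpowered
    )


def compare_pre_post(
    pre_cells: Sequence[CellMeasurement],
    post_cells: Sequence[CellMeasurement],
    config: DAConfig = DAConfig(),
    locus_id: Optional[str] = None,
) -> TreatmentComparison:
    """Pre- vs post-treatment comparison of DA at one locus.

    ``z_pre_post`` is the two-proportion z on the flagged fractions, signed so
    a post-treatment reduction is negative; a reduction is significant when
    z falls below ``reduction_z_threshold`` (-2.0).  ``delta_mu`` is the mean
    per-cell normalized difference of each group, compared by a two-tailed
    Welch t-test.
    """
    if not pre_cells or not post_cells:
        raise ValueError("both pre and post cohorts are required")
    if len(pre_cells) < config.min_cells or len(post_cells) < config.min_cells:
        raise ValueError(f"both cohorts must have >= {config.min_cells} cells")
    pre = summarize_locus(pre_cells, config, locus_id)
    post = summarize_locus(post_cells, config, locus_id)
    z, p, _ = two_proportion_z(
        post.n_da_cells, post.n_cells, pre.n_da_cells, pre.n_cells
    )
    d_pre = np.array([m.normalized_difference for m in pre_cells])
    d_post = np.array([m.normalized_difference for m in post_cells])
    t, df, t_p = welch_t_two_tailed(d_pre, d_post)
    return TreatmentComparison(
        locus_id=pre.locus_id,
        pre=pre,
        post=post,
        z_pre_post=z,
        p_pre_post=p,
        significant_reduction=z < config.reduction_z_threshold,
        delta_mu_pre=float(d_pre.mean()),
        delta_mu_post=float(d_post.mean()),
        t_statistic=t,
        t_df=df,
        t_p_value=t_p,
    )


def welch_t_two_tailed(sample1, sample2):
    """Welch's unequal-variance t-test with Satterthwaite df, two-sided.

    Returns ``(t, df, p)``.  Two zero-variance samples with equal means give
    ``t = 0, p = 1``; with different means the statistic is infinite (p = 0).
    """
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs >= 2 values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    n1, n2 = x.size, y.size
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    diff = x.mean() - y.mean()
    if se2 == 0.0:
        if diff == 0.0:
            return 0.0, float(n1 + n2 - 2), 1.0
        return float(np.sign(diff) * np.inf), float(n1 + n2 - 2), 0.0
    t = diff / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def one_way_anova(groups):
    """Classical one-way ANOVA: ``(F, df_between, df_within, p)``."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs >= 2 values")
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = len(arrays) - 1
    df_within = all_values.size - len(arrays)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, df_between, df_within, 1.0
        return float(np.inf), df_between, df_within, 0.0
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f, df_between, df_within))
    return float(f), df_between, df_within, p


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("samples must have equal length >= 3")
    xc, yc = x - x.mean(), y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))
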
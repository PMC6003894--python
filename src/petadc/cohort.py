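"""Cohort-level statistics on the joined clinical + imaging table.

The cohort table has one row per patient: clinical covariates (histology,
grade, treatment, survival outcomes) joined on patient id with the global
imaging metrics and the per-tumor voxel association result.  Analyses here
are cross-patient Pearson correlations between metrics, two-sided
Mann-Whitney U comparisons between patient groups, and the relationship
between the per-tumor voxel correlation and metabolic tumor volume.

No multiple-testing correction is applied anywhere in this module; p-values
are per-comparison and exploratory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .voxelwise import AssociationResult, fit_association

__all__ = [
    "HISTOLOGIES",
    "GRADES",
    "MannWhitneyResult",
    "metric_correlation",
    "group_compare",
    "correlation_vs_volume",
    "summarize_categorical",
]

HISTOLOGIES = ("SCCA", "AdenoCA", "small_cell", "adenosquamous")
GRADES = ("well", "moderate", "poor")

#: histology groups excluded from two-histology comparisons (single patients)
RARE_HISTOLOGIES = ("small_cell", "adenosquamous")


@dataclass
class MannWhitneyResult:
    """Two-sided Mann-Whitney U comparison of one metric between two groups.

    ``u_a`` counts pairs (a, b) with a < b plus half of the ties; ``u_b`` is
    the complementary statistic (u_a + u_b = n_a * n_b).  Both are reported
    to disambiguate against other software's conventions.  ``method`` is
    'exact' (full null distribution; used when min(n) <= 8 and there are no
    ties) or 'asymptotic' (normal approximation with tie and continuity
    corrections).
    """

    u_a: float
    u_b: float
    p: float
    n_a: int
    n_b: int
    method: str


def _select(cohort: pd.DataFrame, flt) -> pd.DataFrame:
    """Row filter: None (all), a {column: value-or-list} dict, a callable
    returning a boolean mask, or a boolean mask itself."""
    if flt is None:
        return cohort
    if isinstance(flt, dict):
        keep = pd.Series(True, index=cohort.index)
        for col, val in flt.items():
            if col not in cohort.columns:
                raise KeyError(f"unknown column {col!r} in group filter")
            vals = val if isinstance(val, (list, tuple, set)) else [val]
            keep &= cohort[col].isin(list(vals))
        return cohort[keep]
    if callable(flt):
        return cohort[np.asarray(flt(cohort), dtype=bool)]
    return cohort[np.asarray(flt, dtype=bool)]


def _metric_vector(cohort: pd.DataFrame, metric: str) -> np.ndarray:
    if metric not in cohort.columns:
        raise KeyError(f"unknown metric {metric!r}; columns: {list(cohort.columns)}")
    vals = pd.to_numeric(cohort[metric], errors="raise").to_numpy(dtype=np.float64)
    if not np.isfinite(vals).all():
        raise ValueError(f"metric {metric!r} has missing/non-finite values")
    return vals


def metric_correlation(
    cohort: pd.DataFrame, x: str, y: str, subset=None
) -> AssociationResult:
    """Cross-patient Pearson correlation between two global metrics,
    with the two-sided t-test on n-2 degrees of freedom."""
    sub = _select(cohort, subset)
    if len(sub) < 3:
        raise ValueError(
            f"need at least 3 patients for a correlation, got {len(sub)} after subsetting"
        )
    return fit_association(_metric_vector(sub, x), _metric_vector(sub, y))


def correlation_vs_volume(
    cohort: pd.DataFrame,
    subset=None,
    *,
    r_column: str = "voxel_r",
    volume_column: str = "mtv_ml",
) -> AssociationResult:
    """Pearson correlation between the per-tumor voxel SUV-ADC correlation
    coefficient and the metabolic tumor volume across patients."""
    return metric_correlation(cohort, r_column, volume_column, subset=subset)


def group_compare(
    cohort: pd.DataFrame, metric: str, group_a, group_b
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test of one metric between two disjoint
    patient groups.

    The exact null distribution is used when ``min(n_a, n_b) <= 8`` and the
    pooled sample is tie-free; otherwise the normal approximation with tie
    and continuity corrections.  The p-value is invariant under any strictly
    monotone transform of the metric.
    """
    sub_a = _select(cohort, group_a)
    sub_b = _select(cohort, group_b)
    if len(sub_a) == 0 or len(sub_b) == 0:
        raise ValueError(
            f"both groups must be non-empty (sizes {len(sub_a)} and {len(sub_b)})"
        )
    overlap = sub_a.index.intersection(sub_b.index)
    if len(overlap) > 0:
        raise ValueError(f"groups overlap in {len(overlap)} patient(s)")

    a = _metric_vector(sub_a, metric)
    b = _metric_vector(sub_b, metric)
    n_a, n_b = a.size, b.size

    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size

    # rank-sum form: R_a - n_a(n_a+1)/2 counts pairs with a > b (+ ties/2)
    ranks = stats.rankdata(combined)
    u_gt = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)
    u_a = n_a * n_b - u_gt  # pairs with a < b, plus half the ties
    u_b = u_gt

    if float(np.ptp(combined)) == 0.0:
        # complete degeneracy: no separation whatsoever
        return MannWhitneyResult(u_a=u_a, u_b=u_b, p=1.0, n_a=n_a, n_b=n_b, method="degenerate")

    method = "exact" if (min(n_a, n_b) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return MannWhitneyResult(
        u_a=u_a, u_b=u_b, p=float(min(res.pvalue, 1.0)), n_a=n_a, n_b=n_b, method=method
    )


def summarize_categorical(
    clinical: pd.DataFrame,
    columns: tuple[str, ...] = ("histology", "grade", "treatment"),
) -> pd.DataFrame:
    """Cohort composition: per-category counts and percentages (one decimal).

    Returns a tidy frame with columns (characteristic, category, n, percent),
    percentages relative to the number of patients.
    """
    if "id" in clinical.columns and clinical["id"].duplicated().any():
        raise ValueError("duplicate patient ids in clinical table")
    n_total = len(clinical)
    if n_total == 0:
        raise ValueError("empty clinical table")
    rows = []
    for col in columns:
        if col not in clinical.columns:
            raise KeyError(f"clinical table lacks column {col!r}")
        counts = clinical[col].value_counts()
        for category, n in counts.items():
            rows.append(
                {
                    "characteristic": col,
                    "category": category,
                    "n": int(n),
                    "percent": round(100.0 * n / n_total, 1),
                }
            )
    return pd.DataFrame(rows)
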
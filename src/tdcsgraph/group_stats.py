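"""Paired pre/post comparison of graph measures across the density sweep.

For each (group, measure, density) cell the paired differences are tested
for normality (Shapiro-Wilk); normal differences get a paired t-test,
non-normal ones a Wilcoxon signed-rank test.  P-values are then
Benjamini-Hochberg FDR corrected within each (group, measure) family across
the densities of the sweep, and cells are flagged significant at q < 0.05
and q < 0.01.

Samples (overlapping windows) are the default paired units, replicating the
augmented-sample analysis; ``subject_level=True`` averages windows per
subject first, which restores independence of the paired units at the cost
of the augmented sample size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["TestResult", "paired_compare", "fdr_correct", "sweep_compare",
           "results_to_frame"]


@dataclass
class TestResult:
    """Outcome of one paired pre/post comparison after FDR correction."""

    group: str
    measure: str
    density: float
    test_used: str  # "paired_t" | "wilcoxon"
    statistic: float
    p_value: float
    q_value: float
    significant_05: bool
    significant_01: bool
    mean_difference: float  # mean(post - pre), gives the direction of change


def paired_compare(
    pre: Sequence[float],
    post: Sequence[float],
    alpha_normality: float = 0.05,
) -> tuple[str, float, float]:
    """Normality-gated paired test -> (test_used, statistic, two-sided p).

    Shapiro-Wilk on the paired differences selects between the paired t-test
    (differences consistent with normality) and the Wilcoxon signed-rank
    test.  Conventions for degenerate inputs: all differences zero -> p = 1;
    constant nonzero differences (zero variance, every pair shifted
    identically) -> paired t with infinite statistic and p = 0.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    if pre.size < 5:
        raise ValueError("need at least 5 pairs")
    diffs = post - pre
    if np.all(diffs == 0):
        return "paired_t", 0.0, 1.0
    if np.ptp(diffs) == 0:
        return "paired_t", float(np.sign(diffs[0]) * np.inf), 0.0
    shapiro_p = stats.shapiro(diffs).pvalue
    if shapiro_p >= alpha_normality:
        res = stats.ttest_rel(post, pre)
        return "paired_t", float(res.statistic), float(res.pvalue)
    res = stats.wilcoxon(post, pre, zero_method="wilcox")
    return "wilcoxon", float(res.statistic), float(res.pvalue)


def fdr_correct(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, q <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def sweep_compare(
    measures: pd.DataFrame,
    groups: Mapping[str, str],
    alpha_normality: float = 0.05,
    subject_level: bool = False,
) -> list[TestResult]:
    """Paired pre/post tests for every (group, measure, density) cell.

    ``measures`` is a tidy table with columns subject_id, condition,
    window_index, density, measure, value (the per-sample measure table).
    ``groups`` maps subject_id -> group label.  Pre and post values are
    paired by (subject_id, window_index); FDR correction is applied within
    each (group, measure) family across the densities of the sweep.
    """
    required = {"subject_id", "condition", "window_index", "density",
                "measure", "value"}
    missing_cols = required - set(measures.columns)
    if missing_cols:
        raise ValueError(f"measure table missing columns: {sorted(missing_cols)}")
    df = measures.copy()
    df["group"] = df["subject_id"].map(groups)
    if df["group"].isna().any():
        unknown = sorted(df.loc[df["group"].isna(), "subject_id"].unique())
        raise ValueError(f"subjects without group label: {unknown}")
    if subject_level:
        df = (
            df.groupby(
                ["group", "subject_id", "condition", "density", "measure"],
                as_index=False,
            )["value"]
            .mean()
            .assign(window_index=0)
        )

    # NaN measure values (e.g. undefined sigma) become +inf so the pivot
    # keeps the row; non-finite pairs are dropped per cell below, and the
    # unpaired-cell error fires only for genuinely absent samples.
    df["value"] = df["value"].fillna(np.inf)
    wide = df.pivot_table(
        index=["group", "measure", "density", "subject_id", "window_index"],
        columns="condition",
        values="value",
    )
    if "pre" not in wide.columns or "post" not in wide.columns:
        raise ValueError("measure table must contain both pre and post samples")
    incomplete = wide[wide.isna().any(axis=1)]
    if len(incomplete):
        cells = sorted({idx[:3] for idx in incomplete.index})[:10]
        raise ValueError(f"unpaired (group, measure, density) cells: {cells}")

    results: list[TestResult] = []
    for (group, measure), fam in wide.groupby(level=["group", "measure"]):
        fam_results = []
        for density, cell in fam.groupby(level="density"):
            cell = cell.sort_index(level=["subject_id", "window_index"])
            pre = cell["pre"].to_numpy()
            post = cell["post"].to_numpy()
            # sigma can be undefined (NaN) on a per-sample basis; pairs with
            # a missing value are dropped, and cells with fewer than 5
            # usable pairs are reported as missing (p = q = NaN).
            finite = np.isfinite(pre) & np.isfinite(post)
            if finite.sum() >= 5:
                test_used, statistic, p = paired_compare(
                    pre[finite], post[finite], alpha_normality
                )
                mean_diff = float(np.mean(post[finite] - pre[finite]))
            else:
                test_used, statistic, p = "none", np.nan, np.nan
                mean_diff = np.nan
            fam_results.append(
                TestResult(
                    group=group,
                    measure=measure,
                    density=float(density),
                    test_used=test_used,
                    statistic=statistic,
                    p_value=p,
                    q_value=np.nan,
                    significant_05=False,
                    significant_01=False,
                    mean_difference=mean_diff,
                )
            )
        p_vec = np.array([r.p_value for r in fam_results])
        usable = np.isfinite(p_vec)
        q_vec = np.full(p_vec.shape, np.nan)
        if usable.any():
            q_vec[usable] = fdr_correct(p_vec[usable])
        for r, qv in zip(fam_results, q_vec):
            r.q_value = float(qv)
            r.significant_05 = bool(np.isfinite(qv) and qv < 0.05)
            r.significant_01 = bool(np.isfinite(qv) and qv < 0.01)
        results.extend(fam_results)
    return results


def results_to_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    """Tidy DataFrame of sweep results, ordered by group, measure, density."""
    frame = pd.DataFrame([vars(r) for r in results])
    return frame.sort_values(["group", "measure", "density"]).reset_index(drop=True)
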
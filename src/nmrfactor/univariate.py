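"""Per-bin group summaries and unpaired two-sample t-tests.

Mirrors the classical metabolomics convention: per-variable group means ± sd
and an unpaired t-test at p < 0.05. The pooled-variance (Student) test is the
default, Welch is available; Benjamini-Hochberg q-values are always emitted
alongside the raw p-values so users may apply FDR control, but the
``significant`` flag follows the uncorrected per-variable threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import BinnedDataset


def group_summary(
    dataset: BinnedDataset,
    groups: list[str],
    grouping: str = "group",
    variables: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean and sd (n−1 denominator) per (variable, group).

    ``variables`` is an optional bin-index selection. Single-member groups get
    sd = 0 and a ``single_member`` flag.
    """
    labels = dataset.labels(grouping)
    if variables is None:
        variables = np.arange(dataset.n_bins)
    variables = np.asarray(variables, dtype=int)
    rows = []
    for g in groups:
        mask = labels == g
        if not mask.any():
            raise ValueError(f"unknown or empty group {g!r}")
        sub = dataset.matrix[np.ix_(mask, variables)]
        n = sub.shape[0]
        means = sub.mean(axis=0)
        sds = sub.std(axis=0, ddof=1) if n > 1 else np.zeros(sub.shape[1])
        for j, v in enumerate(variables):
            rows.append(
                {
                    "bin_index": int(v),
                    "bin_center": float(dataset.bin_centers[v]),
                    "group": g,
                    "n": n,
                    "mean": float(means[j]),
                    "sd": float(sds[j]),
                    "single_member": n == 1,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class UnivariateResult:
    """Per-variable t-test table for one two-group comparison."""

    table: pd.DataFrame
    comparison: str
    alpha: float
    variant: str


def _degenerate_fix(t: np.ndarray, p: np.ndarray, mean_diff: np.ndarray) -> np.ndarray:
    """Zero pooled variance: equal means -> t=0, p=1; unequal -> p=0."""
    bad = ~np.isfinite(t)
    degenerate = bad.copy()
    equal = bad & (mean_diff == 0)
    t[equal] = 0.0
    p[equal] = 1.0
    unequal = bad & (mean_diff != 0)
    t[unequal] = np.sign(mean_diff[unequal]) * np.inf
    p[unequal] = 0.0
    return degenerate


def unpaired_ttest(
    dataset: BinnedDataset,
    group_a: str,
    group_b: str,
    grouping: str = "group",
    alpha: float = 0.05,
    variant: str = "student",
) -> UnivariateResult:
    """Unpaired two-sample t-test for every bin, group_a vs group_b.

    ``student`` pools variances (df = n_a + n_b − 2); ``welch`` uses the
    Satterthwaite approximation. Two-sided p-values; ``significant`` flags
    p < alpha; BH-adjusted q-values are included.
    """
    labels = dataset.labels(grouping)
    A = dataset.matrix[labels == group_a]
    B = dataset.matrix[labels == group_b]
    for name, M in ((group_a, A), (group_b, B)):
        if M.shape[0] < 2:
            raise ValueError(f"group {name!r} has fewer than 2 samples")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    equal_var = variant == "student"
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(A, B, axis=0, equal_var=equal_var)
    t = np.array(res.statistic, dtype=float, copy=True)
    p = np.array(res.pvalue, dtype=float, copy=True)
    if equal_var:
        df = np.full(dataset.n_bins, float(A.shape[0] + B.shape[0] - 2))
    else:
        df = np.array(res.df, dtype=float, copy=True)
        df[~np.isfinite(df)] = float(A.shape[0] + B.shape[0] - 2)
    mean_diff = A.mean(axis=0) - B.mean(axis=0)
    degenerate = _degenerate_fix(t, p, mean_diff)
    q = multipletests(p, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "bin_center": dataset.bin_centers,
            f"mean_{group_a}": A.mean(axis=0),
            f"sd_{group_a}": A.std(axis=0, ddof=1),
            f"mean_{group_b}": B.mean(axis=0),
            f"sd_{group_b}": B.std(axis=0, ddof=1),
            "t": t,
            "df": df,
            "p": p,
            "q": q,
            "significant": p < alpha,
            "degenerate": degenerate,
        }
    )
    return UnivariateResult(
        table=table, comparison=f"{group_a} vs {group_b}", alpha=alpha, variant=variant
    )
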
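"""Normalisation and two-group differential expression for intensity matrices.

Matrices are features x samples.  Differential calls use an equal-variance
two-sample t-test on log2 quantile-normalised values with Benjamini-Hochberg
adjustment; a feature is differentially expressed when |log2FC| > 1 and
FDR < 0.05 (both strict).  Adjustment is applied across the features handed
to one call, so running mRNA and lncRNA matrices separately yields
per-RNA-type FDR.

The t-test is an ordinary (unmoderated) one; with very small groups its
variance estimates are noisy, which the package accepts as a documented
simplification over empirical-Bayes moderated alternatives.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common reference distribution.

    The reference is the row-wise mean of the sorted columns; ties within a
    column receive the mean of the reference values at their tied ranks.
    """
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values; impute or drop first")
    values = matrix.to_numpy(dtype=float)
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty_like(ref)
        mapped[order] = ref
        # average reference values over ties
        s = pd.Series(mapped)
        out[:, j] = s.groupby(col, sort=False).transform("mean").to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def upper_quartile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each column so its 75th percentile matches the cross-sample mean.

    Offered as the alternative reading of "quartile" normalisation.
    """
    q = matrix.quantile(0.75, axis=0)
    if (q <= 0).any():
        raise ValueError("non-positive upper quartile; cannot scale")
    return matrix / q * q.mean()


def _split_groups(matrix: pd.DataFrame, groups: Mapping[str, str]) -> tuple[list[str], list[str]]:
    ctrl = [s for s in matrix.columns if groups.get(s) in ("ctrl", "control", "normal")]
    case = [s for s in matrix.columns if groups.get(s) in ("uc", "case", "disease")]
    if len(ctrl) < 2 or len(case) < 2:
        raise ValueError(f"need >=2 samples per group (got {len(ctrl)} ctrl, {len(case)} case)")
    return ctrl, case


def differential_expression(
    matrix: pd.DataFrame,
    groups: Mapping[str, str],
    lfc_cut: float = 1.0,
    fdr_cut: float = 0.05,
    is_log2: bool = True,
) -> pd.DataFrame:
    """Per-feature equal-variance t-test (case - ctrl) with BH adjustment.

    Linear-scale input is transformed with log2(x + 1).  Zero-variance
    features with equal group means get p = 1 by convention (p = 0 when the
    means differ).  Output is sorted by FDR, then by |log2FC| descending.
    """
    ctrl_ids, case_ids = _split_groups(matrix, groups)
    values = matrix.to_numpy(dtype=float)
    if not is_log2:
        if (values < 0).any():
            raise ValueError("linear-scale input must be non-negative")
        values = np.log2(values + 1.0)
    df = pd.DataFrame(values, index=matrix.index, columns=matrix.columns)
    ctrl = df[ctrl_ids].to_numpy()
    case = df[case_ids].to_numpy()
    mean_ctrl = ctrl.mean(axis=1)
    mean_case = case.mean(axis=1)
    log2fc = mean_case - mean_ctrl
    import warnings as _warnings

    with _warnings.catch_warnings():
        # near-identical rows trip scipy's precision-loss warning; the
        # degenerate cases are handled explicitly below
        _warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=True)
    # degenerate features: zero pooled variance
    bad = ~np.isfinite(p)
    if bad.any():
        same = np.abs(log2fc) < 1e-12
        p = np.where(bad & same, 1.0, p)
        p = np.where(bad & ~same, 0.0, p)
        t_stat = np.asarray(t_stat, dtype=float).copy()
        t_stat[bad & same] = 0.0
        t_stat[bad & ~same] = np.sign(log2fc[bad & ~same]) * np.inf
    fdr = multipletests(p, method="fdr_bh")[1]
    is_de = (np.abs(log2fc) > lfc_cut) & (fdr < fdr_cut)
    direction = np.where(~is_de, "none", np.where(log2fc > 0, "up", "down"))
    res = pd.DataFrame(
        {
            "feature_id": matrix.index,
            "mean_log2_ctrl": mean_ctrl,
            "mean_log2_case": mean_case,
            "log2fc": log2fc,
            "t_stat": t_stat,
            "p": p,
            "fdr": fdr,
            "is_de": is_de,
            "direction": direction,
        }
    )
    res = res.sort_values(
        ["fdr", "log2fc"], key=lambda c: c.abs() if c.name == "log2fc" else c,
        ascending=[True, False],
    ).reset_index(drop=True)
    return res


def label_swap_check(matrix: pd.DataFrame, groups: Mapping[str, str]) -> dict:
    """Sanity harness: swapping group labels must negate every log2FC and
    leave every p-value unchanged (within 1e-12)."""
    swapped = {s: ("ctrl" if g in ("uc", "case", "disease") else "uc") for s, g in groups.items()}
    a = differential_expression(matrix, groups).set_index("feature_id")
    b = differential_expression(matrix, swapped).set_index("feature_id")
    b = b.loc[a.index]
    max_lfc_residual = float(np.max(np.abs(a["log2fc"] + b["log2fc"])))
    max_p_diff = float(np.max(np.abs(a["p"] - b["p"])))
    ok = max_lfc_residual < 1e-12 and max_p_diff < 1e-12
    return {"max_lfc_residual": max_lfc_residual, "max_p_diff": max_p_diff, "ok": ok}
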
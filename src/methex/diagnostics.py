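"""Logistic diagnostic model, ROC/AUC evaluation and qPCR relative expression.

The classifier is a plain maximum-likelihood logistic regression (no
regularisation) fitted by iteratively reweighted least squares, taking
disease status as the response and expression levels of a gene panel as
predictors.  AUC is the normalised Mann-Whitney statistic (ties count 0.5),
which equals the trapezoidal area under the empirical ROC step curve.
Relative qPCR expression uses the 2^-ddCt rule against a reference gene.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class LogisticModel:
    predictor_ids: list[str]
    coefficients: np.ndarray
    intercept: float
    converged: bool
    n_iter: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "predictor_ids": self.predictor_ids,
                    "coefficients": list(map(float, self.coefficients)),
                    "intercept": float(self.intercept),
                    "converged": self.converged,
                    "n_iter": self.n_iter,
                },
                indent=1,
            )
            + "\n"
        )


def fit_logistic(
    features: pd.DataFrame,
    labels: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticModel:
    """Maximum-likelihood logistic fit by IRLS (samples x predictors input).

    Converges when the largest coefficient change drops below ``tol``.
    Perfect separation shows up as diverging coefficients; the model is then
    flagged ``converged=False`` with a warning, but predictions are still
    usable (probabilities saturate at 0/1).
    """
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    for cls in (0.0, 1.0):
        if (y == cls).sum() < 2:
            raise ValueError("need >=2 samples per class")
    X = features.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing predictor values")
    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    converged = False
    separated = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(Xd @ beta, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = Xd.T * w
        try:
            new_beta = np.linalg.solve(XtW @ Xd, XtW @ z)
        except np.linalg.LinAlgError:
            separated = True
            break
        step = float(np.max(np.abs(new_beta - beta)))
        beta = new_beta
        if np.max(np.abs(beta)) > 1e3:
            separated = True
            break
        if step < tol:
            converged = True
            break
    # perfect separation: every fitted probability saturates at its label
    # (IRLS stalls at the clipping boundary instead of diverging)
    eta = Xd @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    if converged and np.all(np.abs(y - mu) < 1e-6):
        separated = True
    if separated or not converged:
        converged = False
        warnings.warn(
            "logistic fit did not converge (possible perfect separation); "
            "coefficients are unreliable but predictions remain usable",
            RuntimeWarning,
            stacklevel=2,
        )
    return LogisticModel(
        predictor_ids=list(features.columns),
        coefficients=beta[1:],
        intercept=float(beta[0]),
        converged=converged,
        n_iter=it,
    )


def predict_proba(model: LogisticModel, features: pd.DataFrame) -> np.ndarray:
    X = features[model.predictor_ids].to_numpy(dtype=float)
    eta = model.intercept + X @ model.coefficients
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float = field(default=float("nan"))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC step curve and AUC (Mann-Whitney with ties counted 0.5).

    Thresholds sweep the unique score values plus a +inf endpoint; a sample
    is called positive when its score >= threshold.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores, method="average")
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    tpr = np.array([(scores[y == 1] >= t).mean() for t in thresholds])
    fpr = np.array([(scores[y == 0] >= t).mean() for t in thresholds])
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=float(auc))


@dataclass(frozen=True)
class DdctInput:
    ct_target_case: float
    ct_ref_case: float
    ct_target_ctrl: float
    ct_ref_ctrl: float

    def __post_init__(self) -> None:
        for name in ("ct_target_case", "ct_ref_case", "ct_target_ctrl", "ct_ref_ctrl"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def ddct(inp: DdctInput) -> float:
    """Relative expression 2^-ddCt of a target gene, case vs control.

    dCt = Ct(target) - Ct(reference) within each condition; ddCt is the case
    minus control difference.
    """
    dct_case = inp.ct_target_case - inp.ct_ref_case
    dct_ctrl = inp.ct_target_ctrl - inp.ct_ref_ctrl
    return float(2.0 ** (-(dct_case - dct_ctrl)))


def ddct_table(ct: pd.DataFrame, reference: str = "GAPDH") -> pd.DataFrame:
    """Per-gene 2^-ddCt from a long Ct table (sample, group, gene, ct).

    Group-mean Ct values per gene feed the ddCt rule; the reference gene is
    dropped from the output.
    """
    required = {"sample", "group", "gene", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"ct table needs columns {sorted(required)}")
    if reference not in set(ct["gene"]):
        raise ValueError(f"reference gene {reference!r} not in table")
    means = ct.groupby(["gene", "group"], observed=True)["ct"].mean().unstack()
    ctrl_col = next((c for c in means.columns if c in ("ctrl", "control", "normal")), None)
    case_col = next((c for c in means.columns if c in ("uc", "case", "disease")), None)
    if ctrl_col is None or case_col is None:
        raise ValueError("ct table must have a control and a case group")
    rows = []
    for gene in means.index:
        if gene == reference:
            continue
        fold = ddct(
            DdctInput(
                ct_target_case=means.loc[gene, case_col],
                ct_ref_case=means.loc[reference, case_col],
                ct_target_ctrl=means.loc[gene, ctrl_col],
                ct_ref_ctrl=means.loc[reference, ctrl_col],
            )
        )
        rows.append({"gene": gene, "fold_change": fold})
    return pd.DataFrame(rows)
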
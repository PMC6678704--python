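"""Expression proxy signature for alteration burden.

Differential expression between high- and low-burden groups (fold change on
the linear RSEM-like scale, Welch t-test on asinh-transformed values) yields
a candidate gene list; a penalized Cox fit of those genes' expression to
overall survival yields signature coefficients; their weighted sum is the
per-patient expression risk score, dichotomized at the third quartile (high
score associates with low burden, hence worse prognosis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import penalized_cox

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "asinh_transform",
    "differential_expression",
    "expression_risk_score",
    "threshold_risk_score",
    "combined_classifier",
    "derive_signature",
]


@dataclass
class ExpressionMatrix:
    """gene x sample expression values, RSEM-like scale unless transformed."""

    values: pd.DataFrame
    transformed: bool = False

    def __post_init__(self) -> None:
        if not self.transformed and (self.values.to_numpy() < 0).any():
            raise ValueError("untransformed expression must be nonnegative")


def asinh_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise asinh; variance-stabilizing, log-like for large values."""
    if matrix.transformed:
        raise ValueError("expression matrix already asinh-transformed")
    return ExpressionMatrix(values=np.arcsinh(matrix.values), transformed=True)


def differential_expression(
    expr: ExpressionMatrix,
    group_labels: pd.Series,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Genes separating two groups by fold change and Welch t-test.

    Fold change is the ratio of group means on the linear scale, direction-
    symmetric (kept when FC > threshold or FC < 1/threshold); the t-test runs
    on asinh-transformed values.  ``fdr=True`` applies Benjamini-Hochberg to
    the p threshold instead of raw p-values.
    """
    if expr.transformed:
        raise ValueError("differential_expression expects the linear-scale matrix")
    group_labels = pd.Series(group_labels)
    labels = pd.unique(group_labels)
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {list(labels)}")
    common = [s for s in expr.values.columns if s in set(group_labels.index)]
    g1 = [s for s in common if group_labels[s] == labels[0]]
    g2 = [s for s in common if group_labels[s] == labels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least two samples")

    lin = expr.values
    m1 = lin[g1].mean(axis=1)
    m2 = lin[g2].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = m1 / m2
    tr = np.arcsinh(lin)
    a1 = tr[g1].to_numpy()
    a2 = tr[g2].to_numpy()
    var_ok = ~((a1.std(axis=1) == 0) & (a2.std(axis=1) == 0) &
               (a1.mean(axis=1) == a2.mean(axis=1)))
    n_skipped = int((~var_ok).sum())
    if n_skipped:
        logger.warning("differential_expression: %d constant equal-mean genes skipped",
                       n_skipped)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a1, a2, axis=1, equal_var=False)
    out = pd.DataFrame(
        {"fold_change": fc, "t_stat": t, "p_value": p},
        index=lin.index,
    )[var_ok]
    if fdr:
        from statsmodels.stats.multitest import multipletests
        out = out.assign(p_value=multipletests(out["p_value"], method="fdr_bh")[1])
    fc_pass = (out["fold_change"] > fc_threshold) | (out["fold_change"] < 1.0 / fc_threshold)
    keep = fc_pass & (out["p_value"] < p_threshold) & np.isfinite(out["fold_change"])
    result = out[keep].sort_values("p_value")
    result.index.name = "gene"
    return result


def expression_risk_score(
    expr: ExpressionMatrix,
    coefficients: dict[str, float],
) -> pd.Series:
    """Per-patient linear predictor: sum of coef x asinh expression.

    Coefficient genes absent from the matrix contribute 0 (logged).
    """
    if not coefficients:
        raise ValueError("empty coefficient map")
    tr = expr.values if expr.transformed else np.arcsinh(expr.values)
    missing = [g for g in coefficients if g not in tr.index]
    if missing:
        logger.warning("expression_risk_score: %d signature genes missing: %s",
                       len(missing), ", ".join(missing[:10]))
    present = {g: c for g, c in coefficients.items() if g in tr.index}
    score = pd.Series(0.0, index=tr.columns, name="risk_score")
    for g, c in present.items():
        score += c * tr.loc[g]
    return score


def threshold_risk_score(
    scores: pd.Series,
    cutoff: float | None = None,
    quartile: float = 0.75,
) -> tuple[pd.Series, float]:
    """Dichotomize risk scores: >= cutoff is high-risk (worse prognosis).

    With no explicit cutoff the third quartile of the supplied (training)
    scores is used (linear-interpolation quantile).  Returns (labels, cutoff).
    """
    scores = pd.Series(scores)
    if scores.empty:
        raise ValueError("empty scores")
    if cutoff is None:
        if scores.nunique() < 2:
            raise ValueError("constant scores: no quantile cutoff possible")
        cutoff = float(np.quantile(scores.to_numpy(dtype=float), quartile))
    labels = np.where(scores.to_numpy() >= cutoff, "high_risk_expr", "low_risk_expr")
    return pd.Series(labels, index=scores.index, name="expr_group"), float(cutoff)


def combined_classifier(nag_labels: pd.Series, expr_labels: pd.Series) -> pd.Series:
    """Better prognosis iff high burden OR low expression risk."""
    nag_labels = pd.Series(nag_labels)
    expr_labels = pd.Series(expr_labels)
    if not nag_labels.index.equals(expr_labels.index):
        expr_labels = expr_labels.reindex(nag_labels.index)
    if nag_labels.isna().any() or expr_labels.isna().any():
        missing = list(nag_labels.index[nag_labels.isna() | expr_labels.isna()])
        raise ValueError(f"missing labels for patients: {missing[:10]}")
    better = (nag_labels == "high") | (expr_labels == "low_risk_expr")
    return pd.Series(np.where(better, "better", "worse"),
                     index=nag_labels.index, name="prognosis")


def derive_signature(
    expr: ExpressionMatrix,
    time,
    event,
    de_genes,
    alpha: float = 0.1,
    folds: int = 5,
    seed: int = 0,
) -> dict[str, float]:
    """Fit DE genes' expression to OS; nonzero coefficients form the classifier.

    The penalized Cox lambda is chosen by k-fold cross-validated likelihood.
    """
    tr = expr.values if expr.transformed else np.arcsinh(expr.values)
    genes = [g for g in de_genes if g in tr.index]
    if not genes:
        raise ValueError("no candidate genes present in the expression matrix")
    Xg = tr.loc[genes].T.to_numpy(dtype=float)
    fit, _cv = penalized_cox.cross_validate_lambda(
        Xg, time, event, folds=folds, alpha=alpha, seed=seed, feature_names=genes,
    )
    return penalized_cox.extract_panel(fit)
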
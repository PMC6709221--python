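"""Mood component extraction and its relation to module synchronization.

Seven affect survey scores (six negative: anger-affect, anger-hostility,
anger-aggression, fear-affect, fear-somatic, sadness; one positive) are
reduced to a single mood component by PCA on the correlation matrix, with the
sign convention that the positive-affect loading is non-negative. The mood
component is then regressed on candidate within-/between-module
synchronization values by forward-backward stepwise selection, with robust
(bisquare) regression and Spearman correlation as outlier-resistant checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .simulate import AFFECT_COLUMNS

__all__ = [
    "PCResult",
    "StepwiseResult",
    "RobustChecks",
    "first_pc",
    "stepwise_regression",
    "robust_checks",
]


@dataclass
class PCResult:
    scores: np.ndarray
    loadings: pd.Series
    variance_explained: float


@dataclass
class StepwiseResult:
    selected: list
    params: pd.Series
    pvalues: pd.Series
    rsquared: float
    fvalue: float
    f_pvalue: float
    df_model: int
    df_resid: int
    model: object = field(repr=False, default=None)

    @property
    def intercept_only(self) -> bool:
        return len(self.selected) == 0


@dataclass
class RobustChecks:
    robust_slope: float
    robust_p: float
    spearman_rho: float
    spearman_p: float


def first_pc(table: pd.DataFrame, positive_column: str = "positive_affect") -> PCResult:
    """First principal component of the standardized affect scores.

    Columns are z-scored (PCA on the correlation matrix — survey scales
    differ); the component sign is flipped if needed so the positive-affect
    loading is non-negative.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(np.asarray(table, dtype=float), columns=AFFECT_COLUMNS)
    x = table.to_numpy(dtype=float)
    n, k = x.shape
    if n <= k:
        raise ValueError(f"need more subjects ({n}) than score columns ({k})")
    if np.isnan(x).any():
        raise ValueError("affect table contains missing values")
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [c for c, s in zip(table.columns, sd) if s == 0]
        raise ValueError(f"constant affect column(s): {bad}")
    z = (x - x.mean(axis=0)) / sd
    corr = np.corrcoef(z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    vec = eigvecs[:, -1]
    if positive_column in table.columns and vec[list(table.columns).index(positive_column)] < 0:
        vec = -vec
    scores = z @ vec
    return PCResult(
        scores=scores,
        loadings=pd.Series(vec, index=table.columns),
        variance_explained=float(eigvals[-1] / eigvals.sum()),
    )


def _fit_ols(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def stepwise_regression(
    y: np.ndarray,
    candidates: pd.DataFrame,
    enter: float = 0.05,
    remove: float = 0.10,
    max_iter: int = 50,
) -> StepwiseResult:
    """Forward-backward stepwise OLS by coefficient p-value.

    A candidate enters when its partial p-value is below ``enter``; included
    predictors are dropped when their p-value exceeds ``remove``. If nothing
    enters, an intercept-only model is a valid result.
    """
    y = np.asarray(y, dtype=float)
    if not isinstance(candidates, pd.DataFrame):
        candidates = pd.DataFrame(np.asarray(candidates, dtype=float))
        candidates.columns = [f"x{i}" for i in range(candidates.shape[1])]
    if len(y) != len(candidates):
        raise ValueError("y and candidates must have matching lengths")
    selected: list = []
    seen_states = set()
    for _ in range(max_iter):
        changed = False
        # forward step
        best_p, best_c = None, None
        for c in candidates.columns:
            if c in selected:
                continue
            try:
                fit = _fit_ols(y, candidates[selected + [c]])
            except Exception:
                continue
            p = fit.pvalues.get(c, np.nan)
            if np.isfinite(p) and (best_p is None or p < best_p):
                best_p, best_c = p, c
        if best_c is not None and best_p < enter:
            selected.append(best_c)
            changed = True
        # backward step
        if selected:
            fit = _fit_ols(y, candidates[selected])
            pvals = fit.pvalues.drop("const", errors="ignore")
            worst = pvals.idxmax()
            if pvals[worst] > remove:
                selected.remove(worst)
                changed = True
        state = tuple(sorted(selected))
        if not changed or state in seen_states:
            break
        seen_states.add(state)

    if selected:
        fit = _fit_ols(y, candidates[selected])
        return StepwiseResult(
            selected=list(selected),
            params=fit.params,
            pvalues=fit.pvalues,
            rsquared=float(fit.rsquared),
            fvalue=float(fit.fvalue),
            f_pvalue=float(fit.f_pvalue),
            df_model=int(fit.df_model),
            df_resid=int(fit.df_resid),
            model=fit,
        )
    fit = sm.OLS(y, np.ones((len(y), 1))).fit()
    return StepwiseResult(
        selected=[],
        params=pd.Series({"const": float(fit.params[0])}),
        pvalues=pd.Series({"const": float(fit.pvalues[0])}),
        rsquared=0.0,
        fvalue=np.nan,
        f_pvalue=np.nan,
        df_model=0,
        df_resid=int(fit.df_resid),
        model=fit,
    )


def robust_checks(y: np.ndarray, x: np.ndarray) -> RobustChecks:
    """Bisquare robust regression slope test plus Spearman rank correlation."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be matched 1-D arrays")
    if y.size < 10:
        raise ValueError("need at least 10 subjects for the robustness checks")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")
    rlm = sm.RLM(y, sm.add_constant(x), M=sm.robust.norms.TukeyBiweight()).fit()
    rho, sp_p = stats.spearmanr(x, y)
    return RobustChecks(
        robust_slope=float(rlm.params[1]),
        robust_p=float(rlm.pvalues[1]),
        spearman_rho=float(rho),
        spearman_p=float(sp_p),
    )
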
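"""Bidirectional stepwise ordinary least squares with an AIC criterion.

Both network-building engines select regulators by multivariate linear
regression: candidate predictor columns enter and leave the model one at a
time, each move being the single add-or-drop that most improves the Akaike
information criterion, until no move improves it.  Designated columns can be
forced into the model (the perturbed-miRNA indicator in the MPGE engine).

The search is deterministic: candidates are examined in the caller-supplied
order and the first-encountered best move wins ties, so a fixed input always
yields the same model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["OLSFit", "StepwiseResult", "ols_fit", "stepwise_ols"]

# Relative floor on the residual sum of squares inside log(): residuals below
# sqrt(eps)-level of the response scale are numerical noise from an exact fit.
# Flooring makes all exact fits share one AIC log-term so the 2k parameter
# penalty breaks ties among them, instead of float junk doing so.
_RSS_REL_FLOOR = 1e-20


@dataclass
class OLSFit:
    """Least-squares fit of y on [1, X]: coefficients, p-values, AIC."""

    params: pd.Series          # intercept under "const", then one entry per column
    pvalues: pd.Series
    bse: pd.Series
    rss: float
    aic: float
    nobs: int
    df_resid: int

    @property
    def resid_var(self) -> float:
        return self.rss / self.df_resid if self.df_resid > 0 else float("nan")


def ols_fit(y: np.ndarray, X: pd.DataFrame) -> OLSFit:
    """OLS of ``y`` on the columns of ``X`` plus an intercept.

    Coefficient p-values are two-sided t-tests.  A zero residual variance
    yields p = 0 for nonzero coefficients and p = 1 otherwise.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    names = ["const", *X.columns]
    M = np.column_stack([np.ones(n), X.to_numpy(dtype=float)]) if len(X.columns) else np.ones((n, 1))
    k = M.shape[1]
    beta, _, rank, _ = np.linalg.lstsq(M, y, rcond=None)
    if rank < k:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    resid = y - M @ beta
    rss = float(resid @ resid)
    df_resid = n - k
    rss_floor = max(_RSS_REL_FLOOR * float(y @ y), 1e-300)
    aic = n * float(np.log(max(rss, rss_floor) / n)) + 2 * k
    xtx_inv = np.linalg.inv(M.T @ M)
    if df_resid > 0 and rss > rss_floor:
        sigma2 = rss / df_resid
        bse = np.sqrt(sigma2 * np.diag(xtx_inv))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = beta / bse
        pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
    else:
        # saturated or exact fit: infinite precision on nonzero coefficients
        bse = np.zeros(k)
        pvals = np.where(np.abs(beta) > 1e-10, 0.0, 1.0)
    return OLSFit(
        params=pd.Series(beta, index=names),
        pvalues=pd.Series(pvals, index=names),
        bse=pd.Series(bse, index=names),
        rss=rss,
        aic=aic,
        nobs=n,
        df_resid=df_resid,
    )


def _column_addable(M_cols: list[np.ndarray], new: np.ndarray, n: int) -> bool:
    """True if ``new`` is linearly independent of the current design columns."""
    A = np.column_stack([np.ones(n), *M_cols, new])
    return np.linalg.matrix_rank(A) == A.shape[1]


@dataclass
class StepwiseResult:
    """Outcome of a bidirectional stepwise selection."""

    included: list[str]                 # selected columns, in candidate order
    fit: OLSFit                         # final model (includes forced columns)
    forced: tuple[str, ...]
    dropped_collinear: list[str] = field(default_factory=list)
    n_steps: int = 0

    @property
    def params(self) -> pd.Series:
        return self.fit.params

    @property
    def pvalues(self) -> pd.Series:
        return self.fit.pvalues

    @property
    def aic(self) -> float:
        return self.fit.aic


def stepwise_ols(
    y: np.ndarray | pd.Series,
    X: pd.DataFrame,
    candidates: list[str],
    *,
    forced: tuple[str, ...] = (),
    aic_tol: float = 1e-7,
    max_steps: int = 500,
) -> StepwiseResult:
    """Bidirectional (add/drop) stepwise OLS minimising AIC.

    Parameters
    ----------
    y, X : response vector and design frame (no intercept column; one is
        always included internally).
    candidates : columns of ``X`` eligible for selection, in the
        deterministic entry order.
    forced : columns kept in the model unconditionally.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("response / design length mismatch")
    missing = [c for c in (*forced, *candidates) if c not in X.columns]
    if missing:
        raise KeyError(f"columns absent from design: {missing}")

    dropped: list[str] = []

    # Pre-drop candidate columns collinear with the forced block or with an
    # earlier-ordered candidate (the later-ordered column loses).
    kept: list[str] = []
    base_cols = [X[c].to_numpy(dtype=float) for c in forced]
    pool = list(base_cols)
    for c in candidates:
        col = X[c].to_numpy(dtype=float)
        if _column_addable(pool, col, n):
            kept.append(c)
            pool.append(col)
        else:
            dropped.append(c)
            logger.warning("stepwise: dropping collinear candidate column %r", c)

    included: list[str] = list(forced)
    current = ols_fit(y, X[included])
    remaining = list(kept)
    n_steps = 0

    for _ in range(max_steps):
        best_aic = current.aic - aic_tol
        best_move: tuple[str, str] | None = None  # (action, column)
        best_fit: OLSFit | None = None
        cur_cols = [X[c].to_numpy(dtype=float) for c in included]
        for c in remaining:
            col = X[c].to_numpy(dtype=float)
            if not _column_addable(cur_cols, col, n):
                continue
            trial = ols_fit(y, X[[*included, c]])
            if trial.aic < best_aic:
                best_aic, best_move, best_fit = trial.aic, ("add", c), trial
        for c in included:
            if c in forced:
                continue
            trial_cols = [d for d in included if d != c]
            trial = ols_fit(y, X[trial_cols])
            if trial.aic < best_aic:
                best_aic, best_move, best_fit = trial.aic, ("drop", c), trial
        if best_move is None:
            break
        action, col = best_move
        if action == "add":
            included.append(col)
            remaining.remove(col)
        else:
            included.remove(col)
            remaining.append(col)
            remaining.sort(key=kept.index)
        current = best_fit  # type: ignore[assignment]
        n_steps += 1
    else:  # pragma: no cover - pathological oscillation guard
        warnings.warn("stepwise selection hit the step limit", RuntimeWarning)

    # report selected columns in candidate order, forced first
    selected = [c for c in kept if c in included]
    ordered = [*forced, *selected]
    final = ols_fit(y, X[ordered])
    return StepwiseResult(
        included=selected,
        fit=final,
        forced=tuple(forced),
        dropped_collinear=dropped,
        n_steps=n_steps,
    )
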
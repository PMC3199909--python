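"""Differential item functioning screen.

Per item, two nested multinomial logistic regressions of the raw item score:
first on the estimated person location alone, then adding gender, ethnicity
and their interaction.  An item is flagged when the added block is jointly
significant (likelihood-ratio test) AND raises Nagelkerke pseudo-R-squared by
more than the configured threshold (default 3.5 percentage points).  Flagged
items are reported, not removed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.discrete.discrete_model import MNLogit
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .data import ItemBank, ResponseMatrix

__all__ = [
    "MultinomialFit",
    "fit_multinomial_logit",
    "nagelkerke_r2",
    "DifResult",
    "dif_test",
    "dif_screen",
]

DEFAULT_ALPHA = 0.05
DEFAULT_R2_THRESHOLD = 0.035


@dataclass
class MultinomialFit:
    coef: np.ndarray          # (n_predictors+1, K-1), baseline category 0
    loglik: float
    converged: bool
    n_obs: int
    n_categories: int

    @property
    def n_params(self) -> int:
        return int(self.coef.size)


def fit_multinomial_logit(X: np.ndarray, y: np.ndarray,
                          maxiter: int = 200) -> MultinomialFit:
    """ML multinomial logit with intercept; baseline = category 0.

    Non-convergence (including separation) is reported through the
    ``converged`` flag with the capped-iteration estimates, never silently.
    """
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(y).size == X.shape[1]:
        X = X.T
    y = np.asarray(y)
    cats = np.unique(y)
    if cats.size < 2:
        raise ValueError("outcome must have at least 2 observed categories")
    # contiguous recode keeps statsmodels happy with gappy category labels
    recode = {c: i for i, c in enumerate(cats)}
    y_c = np.array([recode[v] for v in y])
    exog = np.column_stack([np.ones(len(y_c)), X])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model = MNLogit(y_c, exog)
        try:
            res = model.fit(method="newton", maxiter=maxiter, disp=0, skip_hessian=True)
            converged = bool(res.mle_retvals.get("converged", False))
        except (PerfectSeparationError, np.linalg.LinAlgError):
            res = model.fit(method="bfgs", maxiter=maxiter, disp=0, skip_hessian=True)
            converged = False
        if not np.all(np.isfinite(np.asarray(res.params))):
            # newton ran off to the boundary (separation); retake with bfgs
            res = model.fit(method="bfgs", maxiter=maxiter, disp=0, skip_hessian=True)
            converged = False
        llf = float(res.llf)  # force lazy evaluation inside the warning guard
    if not np.all(np.isfinite(res.params)) or not np.isfinite(llf):
        converged = False  # separation drove the fit to the boundary
    elif converged and np.abs(res.params).max() > 30:
        converged = False  # runaway coefficients: (quasi-)separation
    return MultinomialFit(
        coef=np.asarray(res.params),
        loglik=llf,
        converged=converged,
        n_obs=len(y_c),
        n_categories=int(cats.size),
    )


def _null_loglik(y: np.ndarray) -> float:
    """Intercept-only multinomial ML log-likelihood (closed form)."""
    _, counts = np.unique(y, return_counts=True)
    n = counts.sum()
    return float((counts * np.log(counts / n)).sum())


def nagelkerke_r2(loglik: float, null_loglik: float, n: int) -> float:
    """Nagelkerke pseudo-R^2 (Cox-Snell rescaled to a unit maximum)."""
    cox_snell = 1.0 - np.exp(2.0 * (null_loglik - loglik) / n)
    max_cs = 1.0 - np.exp(2.0 * null_loglik / n)
    return float(cox_snell / max_cs) if max_cs > 0 else 0.0


@dataclass
class DifResult:
    item_id: int
    lr_statistic: float
    df: int
    p_value: float
    delta_r2: float
    flagged: bool
    notes: str = ""


def dif_test(
    item_responses: np.ndarray,
    theta_hat: np.ndarray,
    gender: np.ndarray,
    ethnicity: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    item_id: int = -1,
) -> DifResult:
    """Nested-model DIF test for one item.

    Model 1: score ~ theta.  Model 2: adds gender, ethnicity and their
    interaction.  df = 3 * (K - 1) for K observed score categories.
    """
    y = np.asarray(item_responses)
    obs = ~pd.isna(y)
    y, th = y[obs].astype(int), np.asarray(theta_hat, float)[obs]
    g, e = np.asarray(gender)[obs].astype(float), np.asarray(ethnicity)[obs].astype(float)

    notes = []
    if np.unique(y).size < 2:
        return DifResult(item_id, 0.0, 0, 1.0, 0.0, False, "constant outcome")
    degenerate = []
    if np.unique(g).size < 2:
        degenerate.append("gender")
    if np.unique(e).size < 2:
        degenerate.append("ethnicity")
    if degenerate:
        return DifResult(
            item_id, 0.0, 0, 1.0, 0.0, False,
            f"constant covariate in subsample: {', '.join(degenerate)}",
        )

    m1 = fit_multinomial_logit(th[:, None], y)
    X2 = np.column_stack([th, g, e, g * e])
    m2 = fit_multinomial_logit(X2, y)
    if not m1.converged or not m2.converged:
        notes.append("non-convergence or separation; estimates capped")

    K = m1.n_categories
    df = 3 * (K - 1)
    lr = max(2.0 * (m2.loglik - m1.loglik), 0.0)
    p = float(chi2.sf(lr, df))
    ll0 = _null_loglik(y)
    delta = nagelkerke_r2(m2.loglik, ll0, len(y)) - nagelkerke_r2(m1.loglik, ll0, len(y))
    flagged = bool(
        m1.converged and m2.converged and p < alpha and delta > r2_threshold
    )
    return DifResult(item_id, lr, df, p, delta, flagged, "; ".join(notes))


def dif_screen(
    responses: ResponseMatrix,
    bank: ItemBank,
    theta_hat: np.ndarray,
    persons: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> pd.DataFrame:
    """Run :func:`dif_test` for every retained item; returns a tidy table."""
    order = pd.Series(np.arange(len(persons)), index=persons["id"])
    idx = order.loc[responses.person_ids].to_numpy()
    gender = persons["gender"].to_numpy()[idx]
    ethnicity = persons["ethnicity"].to_numpy()[idx]
    rows = []
    for j, item_id in enumerate(responses.item_ids):
        if not bank.retained[bank.index_of(int(item_id))]:
            continue
        col = responses.values[:, j]
        obs = ~np.isnan(col)
        res = dif_test(
            col[obs], theta_hat[obs], gender[obs], ethnicity[obs],
            alpha=alpha, r2_threshold=r2_threshold, item_id=int(item_id),
        )
        rows.append(vars(res))
    return pd.DataFrame(rows)
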
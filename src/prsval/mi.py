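"""Chained-equations multiple imputation and Rubin's-rules pooling.

Missing categorical covariates are imputed by a simple fully conditional
specification: each incomplete covariate is modelled by (multinomial)
logistic regression on the other covariates, case status and age, and the
missing cells are drawn from the fitted predictive distribution.  Ten
cycles, covariates visited in order of increasing missingness, M
independent completions.

Estimates computed on the M completed datasets are pooled with Rubin's
rules: pooled point = mean; total variance T = mean within-imputation
variance + (1 + 1/M) x between-imputation variance; degrees of freedom by
the classic large-sample formula nu = (M-1) (1 + W / ((1+1/M) B))^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .cohort import MatchedStudy, _stage_rng

__all__ = ["PooledEstimate", "impute", "rubin_combine"]

N_CYCLES = 10


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of M estimates."""

    theta: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    ci: tuple[float, float]
    M: int

    def __post_init__(self) -> None:
        if self.total_var < self.within_var - 1e-12:
            raise ValueError("total variance cannot fall below the within part")


def rubin_combine(
    estimates, variances, ci_level: float = 0.95
) -> PooledEstimate:
    """Pool M point estimates and their within-imputation variances."""
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.shape != var.shape or est.ndim != 1:
        raise ValueError("estimates and variances must be equal-length vectors")
    if np.any(var < 0):
        raise ValueError("variances must be nonnegative")
    M = len(est)
    if M < 1:
        raise ValueError("need at least one imputation")
    theta = float(est.mean())
    W = float(var.mean())
    if M == 1:
        warnings.warn(
            "single imputation: between-imputation variance undefined, set to 0",
            stacklevel=2,
        )
        B = 0.0
    else:
        B = float(est.var(ddof=1))
    T = W + (1 + 1 / M) * B
    if M > 1 and B > 0:
        df = (M - 1) * (1 + W / ((1 + 1 / M) * B)) ** 2
    else:
        df = np.inf
    half = stats.t.ppf(0.5 + ci_level / 2, df) if np.isfinite(df) else stats.norm.ppf(
        0.5 + ci_level / 2
    )
    margin = half * np.sqrt(T)
    return PooledEstimate(
        theta=theta,
        within_var=W,
        between_var=B,
        total_var=T,
        df=float(df),
        ci=(theta - margin, theta + margin),
        M=M,
    )


def _fit_and_draw(
    target: np.ndarray,
    missing: np.ndarray,
    predictors: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Model observed target values, draw imputations for missing cells."""
    obs = ~missing
    y_obs = target[obs]
    classes = np.unique(y_obs)
    if classes.size == 0:
        raise ValueError("covariate has no observed values to model")
    if classes.size == 1:
        out = target.copy()
        out[missing] = classes[0]
        return out
    model = LogisticRegression(max_iter=500)
    model.fit(predictors[obs], y_obs)
    proba = model.predict_proba(predictors[missing])
    draws = np.array(
        [model.classes_[np.searchsorted(np.cumsum(p), u)]
         for p, u in zip(proba, rng.random(proba.shape[0]))]
    )
    out = target.copy()
    out[missing] = draws
    return out


def impute(study: MatchedStudy, M: int = 10, seed: int = 0) -> list[MatchedStudy]:
    """Return M completed copies of the study (chained equations).

    Case status, set id and age are always complete and always condition
    the imputation models, so the mechanism the generator injects given
    those variables is recoverable.  With no missing data, M identical
    copies are returned.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    df = study.subjects
    covs = study.covariate_names
    miss = {c: df[c].isna().to_numpy() for c in covs}
    incomplete = [c for c in covs if miss[c].any()]
    for c in incomplete:
        if miss[c].all():
            raise ValueError(f"covariate {c!r} has no observed values")
    if not incomplete:
        return [
            MatchedStudy(
                subjects=df.copy(), m=study.m,
                covariate_names=list(covs),
                n_dropped_cases=study.n_dropped_cases,
                dosages=study.dosages,
            )
            for _ in range(M)
        ]
    incomplete.sort(key=lambda c: miss[c].mean())
    base = np.column_stack(
        [df["case"].to_numpy(dtype=float), df["age"].to_numpy(dtype=float)]
    )
    completed = []
    for m_idx in range(M):
        rng = _stage_rng(seed, f"impute-{m_idx}")
        filled = {c: df[c].to_numpy(dtype=float).copy() for c in covs}
        # initial fill: draws from the observed empirical distribution
        for c in incomplete:
            obs_vals = filled[c][~miss[c]]
            filled[c][miss[c]] = rng.choice(obs_vals, size=miss[c].sum())
        for _ in range(N_CYCLES):
            for c in incomplete:
                others = [o for o in covs if o != c]
                X = np.column_stack([base] + [filled[o] for o in others])
                filled[c] = _fit_and_draw(filled[c], miss[c], X, rng)
        out = df.copy()
        for c in covs:
            out[c] = filled[c]
        completed.append(
            MatchedStudy(
                subjects=out, m=study.m,
                covariate_names=list(covs),
                n_dropped_cases=study.n_dropped_cases,
                dosages=study.dosages,
            )
        )
    return completed
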
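"""Conditional and unconditional logistic regression for matched case-control data.

The conditional likelihood for 1:m matched sets (one case, m controls per
set) eliminates the per-set nuisance intercepts: each set contributes the
case's linear predictor minus the log-sum-exp of the linear predictors of
all set members.  Fits use Newton-Raphson with analytic gradient and
Hessian and step-halving on likelihood decrease.

Unconditional logistic regression (used for principal-component selection
and the reclassification models) is delegated to statsmodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import logsumexp

__all__ = [
    "CLRFit",
    "LogisticFit",
    "ORTable",
    "clr_loglik",
    "fit_clr",
    "fit_logistic",
    "or_table",
    "percentile_or_analysis",
]

Z_975 = 1.959964  # two-sided 95% normal quantile


@dataclass
class CLRFit:
    """Result of a conditional-logistic fit on 1:m matched sets."""

    beta: np.ndarray
    covariance: np.ndarray
    loglik: float
    n_sets: int
    iterations: int
    converged: bool
    term_names: list[str] = field(default_factory=list)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    @property
    def zvalues(self) -> np.ndarray:
        return self.beta / self.se

    def summary_frame(self) -> pd.DataFrame:
        names = self.term_names or [f"x{i}" for i in range(len(self.beta))]
        return pd.DataFrame(
            {
                "coef": self.beta,
                "se": self.se,
                "or": np.exp(self.beta),
                "or_lo": np.exp(self.beta - Z_975 * self.se),
                "or_hi": np.exp(self.beta + Z_975 * self.se),
            },
            index=names,
        )


@dataclass
class LogisticFit:
    """Maximum-likelihood unconditional logistic fit (with intercept)."""

    beta: np.ndarray          # [intercept, slopes...]
    covariance: np.ndarray
    loglik: float
    converged: bool
    pvalues: np.ndarray
    term_names: list[str] = field(default_factory=list)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.beta[0] + X @ self.beta[1:]


def _set_groups(sets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (order, boundaries) so rows grouped by set are contiguous.

    ``order`` sorts rows by set label (stable); ``boundaries`` are the start
    indices of each group, suitable for ``np.add.reduceat``.
    """
    sets = np.asarray(sets)
    order = np.argsort(sets, kind="stable")
    sorted_sets = sets[order]
    boundaries = np.flatnonzero(
        np.r_[True, sorted_sets[1:] != sorted_sets[:-1]]
    )
    return order, boundaries


def _validate_sets(case_sorted: np.ndarray, boundaries: np.ndarray) -> None:
    n_cases = np.add.reduceat(case_sorted.astype(int), boundaries)
    if np.any(n_cases != 1):
        bad = int(np.sum(n_cases != 1))
        raise ValueError(
            f"{bad} matched set(s) do not contain exactly one case"
        )


def clr_loglik(
    beta: np.ndarray, X: np.ndarray, sets: np.ndarray, case: np.ndarray
) -> float:
    """Conditional log-likelihood: sum over sets of eta_case - logsumexp(eta).

    Parameters
    ----------
    beta : coefficient vector, shape (p,)
    X : design matrix, shape (n, p); no intercept (it cancels within sets)
    sets : matched-set label per row
    case : binary case indicator per row (exactly one per set)
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and len(np.asarray(sets)) > 1:
        X = X.T
    beta = np.asarray(beta, dtype=float)
    case = np.asarray(case).astype(bool)
    if not (X.shape[0] == len(np.asarray(sets)) == len(case)):
        raise ValueError("design, set labels and case indicator must align")
    order, boundaries = _set_groups(sets)
    _validate_sets(case[order], boundaries)
    eta = X @ beta
    eta_sorted = eta[order]
    ends = np.r_[boundaries[1:], len(eta)]
    lse = np.array([logsumexp(eta_sorted[s:e]) for s, e in zip(boundaries, ends)])
    return float(eta[case].sum() - lse.sum())


def _clr_parts(
    beta: np.ndarray,
    Xs: np.ndarray,
    case_s: np.ndarray,
    boundaries: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log-likelihood, gradient and Hessian on set-sorted data.

    Overflow-safe: within-set probabilities use a per-set max shift.
    """
    n, p = Xs.shape
    eta = Xs @ beta
    ends = np.r_[boundaries[1:], n]
    # per-set max for a stable softmax
    set_idx = np.repeat(np.arange(len(boundaries)), ends - boundaries)
    set_max = np.fmax.reduceat(eta, boundaries)
    shifted = np.exp(eta - set_max[set_idx])
    denom = np.add.reduceat(shifted, boundaries)
    w = shifted / denom[set_idx]  # within-set softmax weights
    ll = float(eta[case_s].sum() - (np.log(denom) + set_max).sum())
    xbar = np.empty((len(boundaries), p))
    for j in range(p):
        xbar[:, j] = np.add.reduceat(w * Xs[:, j], boundaries)
    grad = Xs[case_s].sum(axis=0) - xbar.sum(axis=0)
    # Hessian: -sum_s Cov_s(x) = -sum_s (E[xx'] - xbar xbar')
    Xw = Xs * w[:, None]
    Exx = np.zeros((p, p))
    for j in range(p):
        col = np.add.reduceat(Xw[:, j][:, None] * Xs, boundaries, axis=0)
        Exx[j] = col.sum(axis=0)
    hess = -(Exx - xbar.T @ xbar)
    return ll, grad, hess


def fit_clr(
    X: np.ndarray,
    sets: np.ndarray,
    case: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
    beta0: np.ndarray | None = None,
    term_names: list[str] | None = None,
) -> CLRFit:
    """Fit conditional logistic regression by Newton-Raphson.

    Convergence is declared when the gradient max-norm drops below ``tol``;
    step-halving guards against likelihood decreases.  The covariance is the
    inverse of the negative Hessian at the optimum.  Separation (coefficients
    diverging without the gradient vanishing) raises with diagnostics.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim == 2 and X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(sets)) > 1:
        X = X.T
    case = np.asarray(case).astype(bool)
    if not (X.shape[0] == len(np.asarray(sets)) == len(case)):
        raise ValueError("design, set labels and case indicator must align")
    order, boundaries = _set_groups(sets)
    Xs, case_s = X[order], case[order]
    _validate_sets(case_s, boundaries)
    # columns constant within every set carry no conditional information
    ends = np.r_[boundaries[1:], Xs.shape[0]]
    for j in range(Xs.shape[1]):
        mins = np.minimum.reduceat(Xs[:, j], boundaries)
        maxs = np.maximum.reduceat(Xs[:, j], boundaries)
        if np.all(mins == maxs):
            raise ValueError(
                f"design column {j} is constant within every matched set; "
                "it is not identifiable under the conditional likelihood"
            )
    p = Xs.shape[1]
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    ll, grad, hess = _clr_parts(beta, Xs, case_s, boundaries)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"singular Hessian at iteration {it}; beta={beta}"
            ) from exc
        new_beta = beta - step
        new_ll, new_grad, new_hess = _clr_parts(new_beta, Xs, case_s, boundaries)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step = step / 2.0
            new_beta = beta - step
            new_ll, new_grad, new_hess = _clr_parts(new_beta, Xs, case_s, boundaries)
            halvings += 1
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
    else:
        it = max_iter
    if not converged and np.max(np.abs(grad)) < tol:
        converged = True
    # a vanishing gradient at extreme beta is the signature of separation:
    # the conditional likelihood has its supremum at infinity
    if np.max(np.abs(beta)) > 15:
        raise ValueError(
            "conditional-logistic fit diverged (possible separation): "
            f"|beta|_max={np.max(np.abs(beta)):.1f} after {it} iterations, "
            f"gradient max-norm {np.max(np.abs(grad)):.2e}"
        )
    cov = np.linalg.inv(-hess)
    return CLRFit(
        beta=beta,
        covariance=cov,
        loglik=ll,
        n_sets=len(boundaries),
        iterations=it,
        converged=converged,
        term_names=list(term_names) if term_names else [],
    )


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    term_names: list[str] | None = None,
) -> LogisticFit:
    """Unconditional ML logistic fit with intercept (Newton/IRLS).

    Separation or non-convergence is reported via ``ValueError``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        X = X.T
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("need n > p for a logistic fit")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant; intercept diverges")
    design = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, design).fit(disp=0, maxiter=100)
    if not res.mle_retvals.get("converged", False):
        raise ValueError("logistic fit failed to converge (possible separation)")
    if np.max(np.abs(res.params)) > 50:
        raise ValueError(
            f"logistic fit diverged (possible separation): beta={res.params}"
        )
    names = ["intercept"] + (
        list(term_names) if term_names else [f"x{i}" for i in range(X.shape[1])]
    )
    return LogisticFit(
        beta=np.asarray(res.params),
        covariance=np.asarray(res.cov_params()),
        loglik=float(res.llf),
        converged=True,
        pvalues=np.asarray(res.pvalues),
        term_names=names,
    )


@dataclass
class ORTable:
    """Odds-ratio table with Wald 95% confidence intervals."""

    frame: pd.DataFrame  # columns: label, OR, lo, hi, reference

    def __post_init__(self) -> None:
        f = self.frame
        nonref = ~f["reference"]
        if not (
            (f.loc[nonref, "lo"] <= f.loc[nonref, "OR"] + 1e-12).all()
            and (f.loc[nonref, "OR"] <= f.loc[nonref, "hi"] + 1e-12).all()
        ):
            raise ValueError("CI bounds must bracket the OR")

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def or_table(fit: CLRFit, labels: list[str] | None = None) -> ORTable:
    """OR = exp(beta), 95% CI = exp(beta +/- 1.959964 * se)."""
    if not fit.converged:
        raise ValueError("cannot build an OR table from a non-converged fit")
    labels = labels or fit.term_names or [f"x{i}" for i in range(len(fit.beta))]
    se = fit.se
    frame = pd.DataFrame(
        {
            "label": labels,
            "OR": np.exp(fit.beta),
            "lo": np.exp(fit.beta - Z_975 * se),
            "hi": np.exp(fit.beta + Z_975 * se),
            "reference": False,
        }
    )
    return ORTable(frame)


# seven percentile bands of the control PRS distribution; the middle band
# (40-60%) is the reference in categorical analyses
PERCENTILE_LABELS = [
    "<=10%",
    "10-20%",
    "20-40%",
    "40-60%",
    "60-80%",
    "80-90%",
    ">90%",
]
REFERENCE_CATEGORY = "40-60%"


def percentile_or_analysis(
    categories: np.ndarray | pd.Series,
    sets: np.ndarray,
    case: np.ndarray,
) -> ORTable:
    """Category-wise ORs from one conditional-logistic fit.

    Indicator coding with the 40-60% band as reference; empty categories are
    dropped with a warning.  The reference row is included with OR fixed at 1.
    """
    cats = pd.Series(np.asarray(categories, dtype=object))
    present = [c for c in PERCENTILE_LABELS if (cats == c).any()]
    dropped = [c for c in PERCENTILE_LABELS if c not in present]
    if dropped:
        warnings.warn(f"empty PRS categories dropped: {dropped}", stacklevel=2)
    if REFERENCE_CATEGORY not in present:
        raise ValueError("reference category 40-60% contains no subjects")
    nonref = [c for c in present if c != REFERENCE_CATEGORY]
    X = np.column_stack([(cats == c).to_numpy(dtype=float) for c in nonref])
    fit = fit_clr(X, sets, case, term_names=nonref)
    tab = or_table(fit, labels=nonref).frame
    ref_row = pd.DataFrame(
        {"label": [REFERENCE_CATEGORY], "OR": [1.0], "lo": [np.nan],
         "hi": [np.nan], "reference": [True]}
    )
    ordered = pd.concat([tab, ref_row], ignore_index=True)
    ordered["__k"] = ordered["label"].map({c: i for i, c in enumerate(PERCENTILE_LABELS)})
    ordered = ordered.sort_values("__k").drop(columns="__k").reset_index(drop=True)
    return ORTable(ordered)
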
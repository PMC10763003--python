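"""Discrimination measures for matched case-control designs.

The concordance index accommodating the matching compares scores only
*within* matched sets: over all (case, control) pairs that share a set,
c is the fraction of pairs where the case's score exceeds the control's,
ties counting one half.  Standard errors come from a bootstrap that
resamples whole matched sets, preserving the design.  The combined
questionnaire + polygenic score is built leave-one-set-out: each set is
scored with conditional-logistic coefficients fitted on the remaining sets,
so a subject's combined score never uses her own set's outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .inference import _set_groups, fit_clr

__all__ = [
    "ConcordanceResult",
    "matched_cindex",
    "log_risk_score",
    "bootstrap_se",
    "loo_combined",
    "auc_difference",
]


@dataclass
class ConcordanceResult:
    """Matched c-index with optional bootstrap uncertainty."""

    c: float
    n_pairs: int
    se: float | None = None
    ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.c <= 1.0):
            raise ValueError("c-index must lie in [0,1]")


def _per_set_stats(score, sets, case):
    score = np.asarray(score, dtype=float)
    if np.isnan(score).any():
        raise ValueError("missing score(s); the c-index needs a score per subject")
    case = np.asarray(case).astype(bool)
    if not (len(score) == len(np.asarray(sets)) == len(case)):
        raise ValueError("score, set labels and case indicator must align")
    order, boundaries = _set_groups(sets)
    s, c = score[order], case[order]
    ends = np.r_[boundaries[1:], len(s)]
    wins = np.empty(len(boundaries))
    pairs = np.empty(len(boundaries), dtype=int)
    for g, (b, e) in enumerate(zip(boundaries, ends)):
        cs = s[b:e][c[b:e]]
        if cs.size != 1:
            raise ValueError("each set must contain exactly one case")
        ctrls = s[b:e][~c[b:e]]
        wins[g] = np.sum(cs[0] > ctrls) + 0.5 * np.sum(cs[0] == ctrls)
        pairs[g] = ctrls.size
    return wins, pairs


def matched_cindex(score, sets, case) -> ConcordanceResult:
    """Within-set case-vs-control concordance (ties count 1/2)."""
    wins, pairs = _per_set_stats(score, sets, case)
    return ConcordanceResult(c=float(wins.sum() / pairs.sum()),
                             n_pairs=int(pairs.sum()))


def log_risk_score(risk) -> np.ndarray:
    """Natural log of a 5-year absolute risk, for use as a model score.

    Monotone, so the matched c-index is unchanged versus the raw risk; the
    log scale is the one on which the absolute-risk estimate enters the
    combination and reclassification models.
    """
    risk = np.asarray(risk, dtype=float)
    if np.any(~np.isfinite(risk)) or np.any(risk <= 0) or np.any(risk >= 1):
        raise ValueError("risks must lie strictly in (0,1)")
    return np.log(risk)


def bootstrap_se(
    stat,
    sets,
    B: int = 200,
    seed: int = 0,
    ci_level: float = 0.95,
) -> tuple[float, tuple[float, float], np.ndarray]:
    """Set-level bootstrap of a statistic of the matched study.

    ``stat`` maps an array of set labels (with repetition; a set drawn twice
    contributes twice) to a scalar; whole matched sets are the resampling
    unit so the within-set dependence survives resampling.  Returns
    (se, percentile CI, replicate values).
    """
    if B < 50:
        raise ValueError("B must be >= 50 for a usable bootstrap")
    rng = np.random.default_rng(seed)
    unique_sets = np.unique(np.asarray(sets))
    reps = np.empty(B)
    for b in range(B):
        draw = rng.choice(unique_sets, size=len(unique_sets), replace=True)
        reps[b] = stat(draw)
    lo, hi = np.quantile(reps, [(1 - ci_level) / 2, 1 - (1 - ci_level) / 2])
    return float(reps.std(ddof=1)), (float(lo), float(hi)), reps


def _set_lookup(score, sets, case):
    """Per-set win and pair counts keyed by set label, for fast resampling."""
    wins, pairs = _per_set_stats(score, sets, case)
    order, boundaries = _set_groups(sets)
    labels = np.asarray(sets)[order][boundaries]
    return dict(zip(labels.tolist(), zip(wins, pairs)))


def cindex_bootstrap(
    score, sets, case, B: int = 200, seed: int = 0
) -> ConcordanceResult:
    """Matched c-index with set-bootstrap se and percentile CI."""
    table = _set_lookup(score, sets, case)

    def stat(drawn_sets):
        w = sum(table[s][0] for s in drawn_sets.tolist())
        p = sum(table[s][1] for s in drawn_sets.tolist())
        return w / p

    point = matched_cindex(score, sets, case)
    se, ci, _ = bootstrap_se(stat, sets, B=B, seed=seed)
    return ConcordanceResult(c=point.c, n_pairs=point.n_pairs, se=se, ci=ci)


def loo_combined(
    X: np.ndarray,
    sets,
    case,
    tol: float = 1e-8,
) -> np.ndarray:
    """Leave-one-matched-set-out combined score.

    For every set s, a conditional logistic regression on all other sets
    yields coefficients b_(-s); each member of s is scored b_(-s) . x.
    The full-data fit seeds each leave-one-out fit, which then re-converges
    on its own reduced data.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    sets = np.asarray(sets)
    case = np.asarray(case).astype(bool)
    if X.shape[0] != len(sets):
        X = X.T
    unique_sets = np.unique(sets)
    if len(unique_sets) < 2:
        raise ValueError("need at least 2 matched sets for leave-one-out")
    full = fit_clr(X, sets, case, tol=tol)
    out = np.empty(X.shape[0])
    for s in unique_sets:
        mask = sets == s
        try:
            fit = fit_clr(X[~mask], sets[~mask], case[~mask],
                          tol=tol, beta0=full.beta)
        except ValueError as exc:
            raise ValueError(f"leave-one-out fit failed for set {s!r}: {exc}") from exc
        out[mask] = X[mask] @ fit.beta
    return out


def auc_difference(
    score_a,
    score_b,
    sets,
    case,
    B: int = 200,
    seed: int = 0,
) -> dict:
    """Paired comparison of two scores' matched c-indices.

    delta = c(score_b) - c(score_a); CI by paired set-level bootstrap
    (the same resampled sets evaluate both scores), p two-sided from the
    normal approximation delta / se.
    """
    tab_a = _set_lookup(score_a, sets, case)
    tab_b = _set_lookup(score_b, sets, case)

    def stat(drawn):
        ws_a = sum(tab_a[s][0] for s in drawn.tolist())
        ps = sum(tab_a[s][1] for s in drawn.tolist())
        ws_b = sum(tab_b[s][0] for s in drawn.tolist())
        return ws_b / ps - ws_a / ps

    c_a = matched_cindex(score_a, sets, case).c
    c_b = matched_cindex(score_b, sets, case).c
    delta = c_b - c_a
    se, ci, reps = bootstrap_se(stat, sets, B=B, seed=seed)
    if se == 0:
        p = 1.0
    else:
        p = float(2 * stats.norm.sf(abs(delta) / se))
    return {
        "delta": float(delta),
        "c_a": float(c_a),
        "c_b": float(c_b),
        "se": se,
        "ci": ci,
        "p": p,
    }
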
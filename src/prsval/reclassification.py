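"""Risk reclassification and the categorical net reclassification improvement.

Two nested logistic models are fitted to the case-control data — one with
the log questionnaire absolute risk alone, one adding the polygenic score.
Because a matched case-control sample over-represents cases, the fitted
intercepts target the sampling odds rather than population risk; adding
log{k rho / (1 - rho)} to the linear predictor, with k the control:case
ratio and rho the age-specific 5-year incidence, recalibrates the predicted
probabilities to 5-year absolute risk.  Risks are then cut at 1.66% and
2.5% into three categories and the categorical NRI of Pencina's
case-control formulation is computed:

    NRI = [P(up|case) - P(down|case)] + [P(down|control) - P(up|control)].

Under multiple imputation the NRI is computed per completed dataset and
averaged; its variance pools the per-imputation asymptotic variances with
Rubin's rules.  The presentation cross-tabulation instead averages each
woman's predicted probabilities over the imputations before categorizing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass, field
from scipy import stats
from scipy.special import expit

from .cohort import IncidenceTable
from .inference import LogisticFit, fit_logistic
from .mi import rubin_combine

__all__ = [
    "StudyDesignInfo",
    "RiskCategoryScheme",
    "ReclassCounts",
    "NRIResult",
    "fit_nri_models",
    "intercept_offset",
    "calibrated_risk",
    "categorize",
    "reclass_counts",
    "nri",
    "nri_variance",
    "pooled_nri",
    "averaged_probability_table",
]


@dataclass(frozen=True)
class StudyDesignInfo:
    """Sampling design constants: k controls per case."""

    control_case_ratio: float = 2.0

    def __post_init__(self) -> None:
        if self.control_case_ratio <= 0:
            raise ValueError("control:case ratio must be positive")


@dataclass(frozen=True)
class RiskCategoryScheme:
    """Ordered absolute-risk cut points defining closed-left categories."""

    cuts: tuple[float, ...] = (0.0166, 0.025)
    labels: tuple[str, ...] = ("< 1.66%", "1.66-< 2.5%", ">= 2.5%")

    def __post_init__(self) -> None:
        cuts = tuple(self.cuts)
        if any(not (0 < c < 1) for c in cuts):
            raise ValueError("cut points must lie in (0,1)")
        if any(a >= b for a, b in zip(cuts, cuts[1:])):
            raise ValueError("cut points must be strictly increasing")
        if len(self.labels) != len(cuts) + 1:
            raise ValueError("need one label per category")


@dataclass
class ReclassCounts:
    """Paired cross-tabulations (baseline rows x updated columns)."""

    cases: np.ndarray
    controls: np.ndarray
    labels: tuple[str, ...] = ("< 1.66%", "1.66-< 2.5%", ">= 2.5%")

    def __post_init__(self) -> None:
        self.cases = np.asarray(self.cases, dtype=int)
        self.controls = np.asarray(self.controls, dtype=int)
        for name, mat in (("cases", self.cases), ("controls", self.controls)):
            if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
                raise ValueError(f"{name} table must be square")
            if (mat < 0).any():
                raise ValueError(f"{name} table has negative counts")
        if self.cases.shape != self.controls.shape:
            raise ValueError("case and control tables must have equal shape")

    @property
    def n_cases(self) -> int:
        return int(self.cases.sum())

    @property
    def n_controls(self) -> int:
        return int(self.controls.sum())

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        def frame(mat):
            f = pd.DataFrame(mat, index=self.labels, columns=self.labels)
            f["Total"] = f.sum(axis=1)
            f.loc["Total"] = f.sum(axis=0)
            return f

        return frame(self.cases), frame(self.controls)

    @classmethod
    def from_tsv(cls, path) -> "ReclassCounts":
        """Read the packaged long-format table (group, baseline row, counts)."""
        df = pd.read_csv(path, sep="\t")
        count_cols = [c for c in df.columns if c not in ("group", "baseline_category")]
        mats = {}
        for grp, sub in df.groupby("group", sort=False):
            mats[grp] = sub[count_cols].to_numpy(dtype=int)
        if set(mats) != {"cases", "controls"}:
            raise ValueError("counts file must contain 'cases' and 'controls' groups")
        return cls(cases=mats["cases"], controls=mats["controls"])


@dataclass
class NRIResult:
    """Net reclassification improvement and its components."""

    case_component: float
    control_component: float
    nri: float
    variance: float | None = None
    ci: tuple[float, float] | None = None
    per_imputation: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.isnan(self.case_component) or np.isnan(self.control_component):
            return  # pooled results carry only the combined NRI
        for v in (self.case_component, self.control_component):
            if not (-1.0 - 1e-12 <= v <= 1.0 + 1e-12):
                raise ValueError("NRI components must lie in [-1, 1]")
        if abs(self.nri - (self.case_component + self.control_component)) > 1e-9:
            raise ValueError("nri must equal the sum of its components")


def fit_nri_models(
    case: np.ndarray,
    baseline_score: np.ndarray,
    prs: np.ndarray,
) -> tuple[LogisticFit, LogisticFit]:
    """The two nested logistic models of the reclassification analysis.

    Model 1: case ~ log absolute risk.  Model 2: case ~ log risk + PRS.
    """
    case = np.asarray(case, dtype=float)
    baseline_score = np.asarray(baseline_score, dtype=float)
    prs = np.asarray(prs, dtype=float)
    m1 = fit_logistic(baseline_score[:, None], case, term_names=["log_risk"])
    m2 = fit_logistic(
        np.column_stack([baseline_score, prs]), case,
        term_names=["log_risk", "prs"],
    )
    return m1, m2


def intercept_offset(rho: float, k: float) -> float:
    """Recalibration offset ln(k rho / (1 - rho)).

    Added to the case-control linear predictor it converts sampling odds to
    population 5-year odds: with only an intercept the fitted log-odds is
    ln(1/k), and ln(1/k) + ln(k rho/(1-rho)) = logit(rho).
    """
    if not (0 < rho < 1):
        raise ValueError("rho must lie in (0,1)")
    if k <= 0:
        raise ValueError("control:case ratio k must be positive")
    return float(np.log(k * rho / (1.0 - rho)))


def calibrated_risk(
    model: LogisticFit,
    X: np.ndarray,
    ages: np.ndarray,
    incidence: IncidenceTable,
    design: StudyDesignInfo = StudyDesignInfo(),
) -> np.ndarray:
    """Incidence-calibrated 5-year risk per subject.

    risk_i = expit(eta_i + ln(k rho(age_i) / (1 - rho(age_i)))), where eta
    is the fitted case-control linear predictor (including its intercept).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ages = np.asarray(ages, dtype=float)
    if X.shape[0] != ages.shape[0]:
        X = X.T
    rho = incidence.rho_at(ages)
    offsets = np.log(design.control_case_ratio * rho / (1.0 - rho))
    return expit(model.linear_predictor(X) + offsets)


def categorize(risk, scheme: RiskCategoryScheme = RiskCategoryScheme()) -> np.ndarray:
    """Category index per risk: [0,c1), [c1,c2), [c2,1] (closed-left)."""
    risk = np.asarray(risk, dtype=float)
    if np.any((risk < 0) | (risk > 1)):
        raise ValueError("risks must lie in [0,1]")
    return np.searchsorted(np.asarray(scheme.cuts), risk, side="right")


def reclass_counts(
    cat_base: np.ndarray,
    cat_new: np.ndarray,
    case: np.ndarray,
    n_categories: int = 3,
    labels: tuple[str, ...] | None = None,
) -> ReclassCounts:
    """Cross-tabulate baseline vs updated categories for cases and controls."""
    cat_base = np.asarray(cat_base, dtype=int)
    cat_new = np.asarray(cat_new, dtype=int)
    case = np.asarray(case).astype(bool)
    if not (len(cat_base) == len(cat_new) == len(case)):
        raise ValueError("category and case vectors must be aligned")
    k = n_categories
    def tab(mask):
        mat = np.zeros((k, k), dtype=int)
        np.add.at(mat, (cat_base[mask], cat_new[mask]), 1)
        return mat
    kwargs = {"labels": labels} if labels else {}
    return ReclassCounts(cases=tab(case), controls=tab(~case), **kwargs)


def nri(counts: ReclassCounts) -> NRIResult:
    """Categorical NRI from paired cross-tabulations.

    Cases moving to a higher category count as improvement, controls moving
    lower likewise; each component is the net moved fraction in its group.
    """
    if counts.n_cases == 0 or counts.n_controls == 0:
        raise ValueError("both cases and controls are required for the NRI")
    upper = np.triu(np.ones_like(counts.cases), k=1).astype(bool)
    lower = np.tril(np.ones_like(counts.cases), k=-1).astype(bool)
    case_up = counts.cases[upper].sum()
    case_down = counts.cases[lower].sum()
    ctrl_up = counts.controls[upper].sum()
    ctrl_down = counts.controls[lower].sum()
    case_comp = (case_up - case_down) / counts.n_cases
    ctrl_comp = (ctrl_down - ctrl_up) / counts.n_controls
    return NRIResult(
        case_component=float(case_comp),
        control_component=float(ctrl_comp),
        nri=float(case_comp + ctrl_comp),
    )


def nri_variance(counts: ReclassCounts) -> float:
    """Asymptotic variance of the categorical NRI (Pencina-style).

    Each component is a difference of multinomial proportions, so
    var = [p_up + p_down - (p_up - p_down)^2] / n within each group and the
    two group variances add.
    """
    upper = np.triu(np.ones_like(counts.cases), k=1).astype(bool)
    lower = np.tril(np.ones_like(counts.cases), k=-1).astype(bool)

    def part(mat, n):
        pu = mat[upper].sum() / n
        pdn = mat[lower].sum() / n
        return (pu + pdn - (pu - pdn) ** 2) / n

    return float(
        part(counts.cases, counts.n_cases)
        + part(counts.controls, counts.n_controls)
    )


def pooled_nri(
    nris,
    variances,
    ci_level: float = 0.95,
) -> NRIResult:
    """Average per-imputation NRIs; Rubin's rules for the variance.

    The point estimate is the plain mean of the per-imputation NRIs; the
    CI is normal-approximate on the pooled total variance.
    """
    nris = np.asarray(nris, dtype=float)
    pooled = rubin_combine(nris, variances, ci_level=ci_level)
    z = stats.norm.ppf(0.5 + ci_level / 2)
    half = z * np.sqrt(pooled.total_var)
    return NRIResult(
        case_component=float("nan"),
        control_component=float("nan"),
        nri=pooled.theta,
        variance=pooled.total_var,
        ci=(pooled.theta - half, pooled.theta + half),
        per_imputation=[float(v) for v in nris],
    )


def averaged_probability_table(
    risks_base: np.ndarray,
    risks_new: np.ndarray,
    case: np.ndarray,
    scheme: RiskCategoryScheme = RiskCategoryScheme(),
) -> ReclassCounts:
    """Presentation table: average each subject's risks over imputations first.

    ``risks_base`` and ``risks_new`` are (M x n) or (n,) arrays of per-
    imputation predicted risks; each woman's mean risk across imputations is
    categorized once, then cross-tabulated.  This is a presentation choice:
    it does not generally equal the mean of the per-imputation tables.
    """
    rb = np.atleast_2d(np.asarray(risks_base, dtype=float))
    rn = np.atleast_2d(np.asarray(risks_new, dtype=float))
    if rb.shape != rn.shape:
        raise ValueError("risk matrices must have equal shape")
    mean_b = rb.mean(axis=0)
    mean_n = rn.mean(axis=0)
    return reclass_counts(
        categorize(mean_b, scheme), categorize(mean_n, scheme), case,
        n_categories=len(scheme.labels), labels=scheme.labels,
    )
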
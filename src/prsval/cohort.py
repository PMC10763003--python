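"""Synthetic cohorts with risk-set-sampled matched case-control studies.

Emulates a prospective cohort followed by biennial questionnaire: subjects
enter at a given age, genotypes are drawn in Hardy-Weinberg proportions
(optionally from two subpopulations with diverged allele frequencies),
incident events occur at 2-year cycle resolution under a log-additive risk
model, and for every incident case ``m`` controls still event-free at the
case's diagnosis cycle are sampled exactly matched on year of age.

The questionnaire-based absolute-risk estimate is built from the
epidemiologic covariates only, never from genotype, so its correlation with
the polygenic score is near zero by construction — the structure the
downstream score-combination analysis assumes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .prs import DosageMatrix, WeightPanel

__all__ = [
    "CohortParams",
    "Population",
    "MatchedStudy",
    "IncidenceTable",
    "default_incidence_table",
    "DEFAULT_COVARIATE_EFFECTS",
    "generate_weights",
    "generate_population",
    "risk_set_sample",
    "inject_missingness",
]

#: log-odds per indicator for the Table-1-style questionnaire covariates,
#: scaled so the questionnaire risk score alone discriminates at AUC ~0.58,
#: the level reported for questionnaire-only absolute-risk models in this
#: population.  Signs follow the epidemiology: family history and biopsy
#: raise risk, adolescent overweight and breastfeeding lower it.
DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "fam_hist_breast": 0.40,
    "fam_hist_prostate": 0.10,
    "early_menarche": 0.20,
    "breastfed_ever": -0.10,
    "oc_use_5yr": 0.20,
    "oophorectomy": -0.10,
    "high_bmi_18": -0.30,
    "high_bmi_current": 0.05,
    "biopsy_ever": 0.25,
}

#: marginal prevalence of each covariate indicator (control-like values)
COVARIATE_PREVALENCE: dict[str, float] = {
    "fam_hist_breast": 0.20,
    "fam_hist_prostate": 0.19,
    "early_menarche": 0.79,
    "breastfed_ever": 0.44,
    "oc_use_5yr": 0.33,
    "oophorectomy": 0.12,
    "high_bmi_18": 0.13,
    "high_bmi_current": 0.40,
    "biopsy_ever": 0.35,
}

COVARIATE_NAMES = list(DEFAULT_COVARIATE_EFFECTS)

#: ER-positive share among subtyped cases (555 ER+ vs 296 ER- in the
#: validation case series) and the share of cases with unknown ER status.
ER_POSITIVE_SHARE = 555 / (555 + 296)
ER_UNKNOWN_SHARE = 71 / 922


@dataclass(frozen=True)
class IncidenceTable:
    """Age-band 5-year incidence probabilities rho (half-open bands)."""

    age_lo: np.ndarray
    age_hi: np.ndarray
    rho: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.age_lo, dtype=float)
        hi = np.asarray(self.age_hi, dtype=float)
        rho = np.asarray(self.rho, dtype=float)
        if not (np.all(rho > 0) and np.all(rho < 1)):
            raise ValueError("incidence probabilities must lie in (0,1)")
        if not np.all(lo < hi):
            raise ValueError("bands need age_lo < age_hi")
        if not np.all(lo[1:] == hi[:-1]):
            raise ValueError("age bands must partition the range contiguously")
        object.__setattr__(self, "age_lo", lo)
        object.__setattr__(self, "age_hi", hi)
        object.__setattr__(self, "rho", rho)

    def band_index(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        idx = np.searchsorted(self.age_lo, age, side="right") - 1
        bad = (idx < 0) | (age >= self.age_hi[-1])
        if np.any(bad):
            raise ValueError(
                f"age(s) outside incidence table range "
                f"[{self.age_lo[0]}, {self.age_hi[-1]}): "
                f"{np.unique(np.asarray(age)[bad])[:5]}"
            )
        return idx

    def rho_at(self, age) -> np.ndarray:
        """5-year incidence probability for each age."""
        return self.rho[self.band_index(age)]

    def two_year_prob(self, age) -> np.ndarray:
        """Per-cycle (2-year) event probability from the 5-year rho."""
        return 1.0 - (1.0 - self.rho_at(age)) ** (2.0 / 5.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age_lo": self.age_lo, "age_hi": self.age_hi, "rho": self.rho}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "IncidenceTable":
        df = pd.read_csv(path, sep="\t")
        return cls(df["age_lo"].to_numpy(), df["age_hi"].to_numpy(),
                   df["rho"].to_numpy())


def default_incidence_table() -> IncidenceTable:
    """Synthetic age-specific 5-year incidence table.

    A smooth stand-in with the shape and scale of published 5-year breast
    cancer incidence for US Black women (rising from ~0.3% in the early 30s
    to ~2% past age 60); it is not an extract of any registry table.
    """
    age_lo = np.array([30, 35, 40, 45, 50, 55, 60, 65, 70, 75], dtype=float)
    age_hi = np.array([35, 40, 45, 50, 55, 60, 65, 70, 75, 90], dtype=float)
    rho = np.array(
        [0.0030, 0.0050, 0.0080, 0.0110, 0.0130, 0.0160, 0.0190,
         0.0210, 0.0220, 0.0220]
    )
    return IncidenceTable(age_lo, age_hi, rho)


@dataclass
class CohortParams:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the scale and signal structure of the validation
    study: ~15,000 at-risk subjects followed for twelve 2-year cycles yield
    on the order of 900 incident cases, the per-SD polygenic effect is
    ln(1.42), and the covariate effects give the questionnaire score an AUC
    near 0.58.
    """

    n_subjects: int = 15_000
    n_variants: int = 500
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    n_subpops: int = 1
    subpop_freq_divergence: float = 0.0
    prs_effect: float = float(np.log(1.42))
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    baseline_incidence: IncidenceTable = field(
        default_factory=default_incidence_table
    )
    n_cycles: int = 12
    age_range: tuple[int, int] = (30, 64)
    er_positive_share: float = ER_POSITIVE_SHARE
    er_unknown_share: float = ER_UNKNOWN_SHARE
    questionnaire_coef_scale: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.allele_freq_range
        if not (0 < lo < hi < 1):
            raise ValueError("allele_freq_range must satisfy 0 < lo < hi < 1")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0,1)")
        if self.n_subpops not in (1, 2):
            raise ValueError("n_subpops must be 1 or 2")


@dataclass
class Population:
    """A simulated cohort: covariates, genotypes, events and risk estimates."""

    subjects: pd.DataFrame     # id, age_entry, subpop, covariates...,
                               # true_lp, event_cycle, er_status, risk_estimate
    dosages: DosageMatrix
    params: CohortParams
    covariate_names: list[str] = field(default_factory=lambda: list(COVARIATE_NAMES))
    questionnaire_coefs: dict[str, float] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.subjects)


@dataclass
class MatchedStudy:
    """Risk-set-sampled 1:m matched study.

    ``subjects`` has one row per study member with columns subject_id,
    set_id, case, er_status, age (index age-year), cycle (index cycle),
    the covariates, and risk_estimate (5-year questionnaire risk at the
    index age).
    """

    subjects: pd.DataFrame
    m: int
    covariate_names: list[str] = field(default_factory=lambda: list(COVARIATE_NAMES))
    n_dropped_cases: int = 0
    dosages: DosageMatrix | None = None

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_sets(self) -> int:
        return self.subjects["set_id"].nunique()

    @property
    def sets(self) -> np.ndarray:
        return self.subjects["set_id"].to_numpy()

    @property
    def case(self) -> np.ndarray:
        return self.subjects["case"].to_numpy().astype(bool)

    def validate(self) -> None:
        g = self.subjects.groupby("set_id")
        if not (g["case"].sum() == 1).all():
            raise ValueError("every matched set must contain exactly one case")
        if not (g.size() == self.m + 1).all():
            raise ValueError(f"every set must have 1 case and {self.m} controls")
        if not (g["age"].nunique() == 1).all():
            raise ValueError("set members must share the index age-year")
        if not (g["cycle"].nunique() == 1).all():
            raise ValueError("set members must share the index cycle")

    def design(self, columns: list[str]) -> np.ndarray:
        return self.subjects[columns].to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        self.subjects.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, covariate_names: list[str] | None = None) -> "MatchedStudy":
        df = pd.read_csv(path, sep="\t")
        m = int(df.groupby("set_id").size().iloc[0]) - 1
        fixed = {"subject_id", "set_id", "case", "er_status", "age", "cycle",
                 "risk_estimate"}
        covs = covariate_names or [c for c in df.columns if c not in fixed]
        return cls(subjects=df, m=m, covariate_names=covs)


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Fixed seed-splitting rule: one global seed fans out per stage."""
    child = (int(seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)
    return np.random.default_rng(child)


def generate_weights(
    n_variants: int,
    subtype_mode: bool = False,
    seed: int = 0,
    weight_scale: float = 0.05,
    allele_freq_range: tuple[float, float] = (0.05, 0.95),
) -> WeightPanel | tuple[WeightPanel, WeightPanel]:
    """Draw a synthetic per-allele weight panel.

    Weights are N(0, weight_scale^2) on the log-odds scale.  With
    ``subtype_mode`` two overlapping panels tagged ER-positive and
    ER-negative are returned (they share ~half their variants, mirroring
    subtype scores built on partly shared architecture).
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    rng = _stage_rng(seed, "weights")
    alleles = np.array(list("ACGT"))
    ids = np.array([f"rs{i:06d}" for i in range(n_variants)])
    eff_idx = rng.integers(0, 4, size=n_variants)
    # pick the other allele uniformly among the remaining three
    oth_idx = (eff_idx + rng.integers(1, 4, size=n_variants)) % 4
    freqs = rng.uniform(*allele_freq_range, size=n_variants)

    def _panel(weights: np.ndarray, subtype: str, mask=None) -> WeightPanel:
        sel = slice(None) if mask is None else mask
        df = pd.DataFrame(
            {
                "variant_id": ids[sel],
                "effect_allele": alleles[eff_idx[sel]],
                "other_allele": alleles[oth_idx[sel]],
                "weight": weights[sel],
                "subtype": subtype,
                "info": np.ones(len(ids[sel])),
                "freq": freqs[sel],
            }
        )
        return WeightPanel(df)

    if not subtype_mode:
        w = rng.normal(0.0, weight_scale, size=n_variants)
        return _panel(w, "overall")
    # two mostly disjoint subtype panels with a small shared core, mirroring
    # subtype scores whose union forms the overall panel (shares taken from
    # the 29,299 ER+ / 28,392 ER- / 56,920-union composition)
    u = rng.random(n_variants)
    shared = u < 0.0135
    pos_only = (u >= 0.0135) & (u < 0.0135 + 0.5012)
    neg_only = ~shared & ~pos_only
    w_pos = rng.normal(0.0, weight_scale, size=n_variants)
    w_neg = np.where(shared, w_pos * 0.8 + rng.normal(0.0, 0.6 * weight_scale, n_variants),
                     rng.normal(0.0, weight_scale, size=n_variants))
    return (
        _panel(w_pos, "ER-positive", shared | pos_only),
        _panel(w_neg, "ER-negative", shared | neg_only),
    )


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    cols = {
        name: (rng.random(n) < p).astype(float)
        for name, p in COVARIATE_PREVALENCE.items()
    }
    return pd.DataFrame(cols)


def generate_population(params: CohortParams, weights: WeightPanel) -> Population:
    """Simulate the cohort forward through its questionnaire cycles.

    Genotypes are Binomial(2, f) per variant; with two subpopulations the
    frequencies are shifted apart by ``subpop_freq_divergence``.  The
    per-cycle event probability is the age-specific 2-year baseline times
    exp(linear predictor), with the predictor centred so the marginal rate
    tracks the baseline table; probabilities reaching 1 raise an error.
    """
    if len(weights) != params.n_variants:
        raise ValueError(
            f"weight panel has {len(weights)} variants, params expect "
            f"{params.n_variants}"
        )
    rng_geno = _stage_rng(params.seed, "genotypes")
    rng_cov = _stage_rng(params.seed, "covariates")
    rng_event = _stage_rng(params.seed, "events")
    n, v = params.n_subjects, params.n_variants

    freqs = weights.df["freq"].to_numpy() if "freq" in weights.df else np.full(v, 0.3)
    subpop = np.zeros(n, dtype=int)
    if params.n_subpops == 2:
        subpop = (rng_geno.random(n) < 0.5).astype(int)
        shift = params.subpop_freq_divergence * (rng_geno.random(v) - 0.5) * 2
        f0 = np.clip(freqs - shift / 2, 0.01, 0.99)
        f1 = np.clip(freqs + shift / 2, 0.01, 0.99)
        fmat = np.where(subpop[:, None] == 0, f0[None, :], f1[None, :])
        dos = rng_geno.binomial(2, fmat).astype(float)
    else:
        dos = rng_geno.binomial(2, freqs[None, :].repeat(n, axis=0)).astype(float)

    covs = _draw_covariates(rng_cov, n)
    ages = rng_cov.integers(params.age_range[0], params.age_range[1] + 1, size=n)

    w = weights.df["weight"].to_numpy()
    raw_prs = dos @ w
    sd = raw_prs.std()
    z_prs = (raw_prs - raw_prs.mean()) / (sd if sd > 0 else 1.0)

    eff = params.covariate_effects
    lp_cov = sum(
        eff.get(name, 0.0) * covs[name].to_numpy() for name in COVARIATE_NAMES
    )
    lp = lp_cov + params.prs_effect * z_prs
    # centre so the cohort-average relative risk is ~1 and margins track rho
    rr = np.exp(lp)
    rr = rr / rr.mean()

    q_coefs = {k: v_ * params.questionnaire_coef_scale for k, v_ in eff.items()}
    lp_q = sum(q_coefs.get(nm, 0.0) * covs[nm].to_numpy() for nm in COVARIATE_NAMES)
    rr_q = np.exp(lp_q)
    rr_q_norm = float(np.exp(lp_q).mean())

    table = params.baseline_incidence
    event_cycle = np.full(n, -1, dtype=int)
    alive = np.ones(n, dtype=bool)
    for c in range(1, params.n_cycles + 1):
        age_c = ages + 2 * (c - 1)
        p2 = table.two_year_prob(age_c) * rr
        if np.any(p2 >= 1.0):
            raise ValueError(
                "per-cycle event probability reached 1; reduce effect sizes "
                f"(max p={p2.max():.3f} at cycle {c})"
            )
        hits = alive & (rng_event.random(n) < p2)
        event_cycle[hits] = c
        alive &= ~hits

    er_status = np.array(["none"] * n, dtype=object)
    is_event = event_cycle > 0
    u = rng_event.random(n)
    typed = u >= params.er_unknown_share
    u2 = rng_event.random(n)
    er_status[is_event & ~typed] = "unknown"
    er_status[is_event & typed & (u2 < params.er_positive_share)] = "positive"
    er_status[is_event & typed & (u2 >= params.er_positive_share)] = "negative"

    risk_entry = np.clip(table.rho_at(ages) * rr_q / rr_q_norm, 1e-6, 1 - 1e-6)

    subjects = pd.DataFrame({"subject_id": np.arange(n), "age_entry": ages,
                             "subpop": subpop})
    subjects = pd.concat([subjects, covs], axis=1)
    subjects["true_lp"] = lp
    subjects["event_cycle"] = event_cycle
    subjects["er_status"] = er_status
    subjects["risk_estimate"] = risk_entry

    dosmat = DosageMatrix(
        values=dos,
        subject_ids=subjects["subject_id"].to_numpy(),
        variant_ids=weights.df["variant_id"].to_numpy(),
        counted_allele=weights.df["effect_allele"].to_numpy(),
        other_allele=weights.df["other_allele"].to_numpy(),
    )
    return Population(
        subjects=subjects,
        dosages=dosmat,
        params=params,
        questionnaire_coefs={**q_coefs, "_norm": rr_q_norm},
    )


def risk_set_sample(
    pop: Population, m: int = 2, seed: int = 0
) -> MatchedStudy:
    """Sample ``m`` controls per incident case from the case's risk set.

    Eligible controls share the case's year of age at the index cycle and
    are event-free at that cycle; a sampled control whose own event occurs
    later appears again as a case of a later set.  Each subject serves as a
    control at most once.  Cases with fewer than ``m`` eligible controls
    are dropped and counted.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = _stage_rng(seed, "risk-set")
    subj = pop.subjects
    event_cycle = subj["event_cycle"].to_numpy()
    ages = subj["age_entry"].to_numpy()
    cases = np.flatnonzero(event_cycle > 0)
    if cases.size == 0:
        raise ValueError("population contains no events to sample around")
    # process cases in time order so earlier sets can reuse later cases
    order = cases[np.argsort(event_cycle[cases], kind="stable")]
    used_as_control: set[int] = set()
    table = pop.params.baseline_incidence
    q_norm = pop.questionnaire_coefs.get("_norm", 1.0)
    covs = {nm: subj[nm].to_numpy() for nm in pop.covariate_names}
    lp_q = sum(
        pop.questionnaire_coefs.get(nm, 0.0) * covs[nm]
        for nm in pop.covariate_names
    )
    rr_q = np.exp(lp_q) / q_norm

    rows = []
    dropped = 0
    set_id = 0
    for i in order:
        c = event_cycle[i]
        index_age = ages[i] + 2 * (c - 1)
        eligible = np.flatnonzero(
            (ages == ages[i])
            & ((event_cycle < 0) | (event_cycle > c))
        )
        eligible = np.array(
            [j for j in eligible if j != i and j not in used_as_control],
            dtype=int,
        )
        if eligible.size < m:
            dropped += 1
            continue
        picks = rng.choice(eligible, size=m, replace=False)
        used_as_control.update(int(j) for j in picks)
        members = np.r_[i, picks]
        risk = np.clip(table.rho_at(np.full(m + 1, index_age)) * rr_q[members],
                       1e-6, 1 - 1e-6)
        for k, j in enumerate(members):
            rows.append(
                {
                    "subject_id": int(subj["subject_id"].iloc[j]),
                    "set_id": set_id,
                    "case": int(k == 0),
                    "er_status": subj["er_status"].iloc[j] if k == 0 else "none",
                    "age": int(index_age),
                    "cycle": int(c),
                    **{nm: covs[nm][j] for nm in pop.covariate_names},
                    "risk_estimate": float(risk[k]),
                }
            )
        set_id += 1
    if not rows:
        raise ValueError("no matched set could be formed (all cases dropped)")
    frame = pd.DataFrame(rows)
    study_ids = frame["subject_id"].to_numpy()
    dosages = pop.dosages.subset_subjects(study_ids)
    return MatchedStudy(
        subjects=frame,
        m=m,
        covariate_names=list(pop.covariate_names),
        n_dropped_cases=dropped,
        dosages=dosages,
    )


def questionnaire_risk(
    subjects: pd.DataFrame,
    coefs: dict[str, float],
    incidence: IncidenceTable,
    covariate_names: list[str],
    ages: np.ndarray | None = None,
) -> np.ndarray:
    """5-year absolute risk from the questionnaire covariates alone.

    risk = rho(age) * exp(sum_j c_j x_j) / norm, clipped to (0,1); ``coefs``
    may carry the normalizing constant under the key ``"_norm"`` (the
    cohort-average relative risk at generation time).
    """
    ages = subjects["age"].to_numpy() if ages is None else np.asarray(ages)
    lp = np.zeros(len(subjects))
    for nm in covariate_names:
        lp += coefs.get(nm, 0.0) * subjects[nm].to_numpy(dtype=float)
    rr = np.exp(lp) / coefs.get("_norm", 1.0)
    return np.clip(incidence.rho_at(ages) * rr, 1e-6, 1 - 1e-6)


def inject_missingness(
    study: MatchedStudy,
    rate: float,
    mechanism: str = "MCAR",
    seed: int = 0,
    case_rate_ratio: float = 2.0,
) -> MatchedStudy:
    """Blank covariate cells at the given rate; design fields are never masked.

    ``MCAR`` masks every covariate cell independently; ``MAR`` conditions on
    case status, masking cases at ``rate * case_rate_ratio`` and controls at
    ``rate`` (the observed design variables drive the mechanism, so the
    missingness is at random given the retained data).
    """
    if not (0 <= rate < 1):
        raise ValueError("rate must be in [0,1)")
    if mechanism not in ("MCAR", "MAR"):
        raise ValueError("mechanism must be 'MCAR' or 'MAR'")
    if rate == 0:
        return study
    rng = _stage_rng(seed, "missingness")
    df = study.subjects.copy()
    n = len(df)
    if mechanism == "MCAR":
        cell_rate = np.full(n, rate)
    else:
        cell_rate = np.where(
            df["case"].to_numpy() == 1,
            min(rate * case_rate_ratio, 0.99),
            rate,
        )
    for nm in study.covariate_names:
        mask = rng.random(n) < cell_rate
        col = df[nm].astype(float).to_numpy()
        col[mask] = np.nan
        df[nm] = col
    return MatchedStudy(
        subjects=df,
        m=study.m,
        covariate_names=list(study.covariate_names),
        n_dropped_cases=study.n_dropped_cases,
        dosages=study.dosages,
    )
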
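"""End-to-end orchestration: simulate -> score -> validate -> combine -> NRI.

``run_validation`` executes the full matched-study analysis on simulated (or
pre-built) inputs and returns one JSON-serializable report: per-SD and
percentile odds ratios from conditional logistic regression, matched
c-indices (questionnaire model, polygenic score, leave-one-set-out combined
score) pooled over multiple imputations with Rubin's rules, the paired AUC
difference, incidence-calibrated reclassification tables and the pooled
categorical NRI.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort import (
    CohortParams,
    IncidenceTable,
    MatchedStudy,
    default_incidence_table,
    generate_population,
    generate_weights,
    inject_missingness,
    questionnaire_risk,
    risk_set_sample,
)
from .discrimination import (
    auc_difference,
    cindex_bootstrap,
    log_risk_score,
    loo_combined,
    matched_cindex,
)
from .inference import fit_clr, or_table, percentile_or_analysis
from .mi import impute, rubin_combine
from .prs import (
    combine_subtypes,
    filter_low_info,
    prune_and_pca,
    score,
    select_pcs,
    standardize_and_categorize,
)
from .reclassification import (
    ReclassCounts,
    RiskCategoryScheme,
    StudyDesignInfo,
    averaged_probability_table,
    calibrated_risk,
    categorize,
    fit_nri_models,
    nri,
    nri_variance,
    pooled_nri,
    reclass_counts,
)

__all__ = ["RunConfig", "run_validation", "table3_check", "packaged_counts_path"]

log = logging.getLogger("prsval")


@dataclass
class RunConfig:
    """One configuration object drives a full validation run."""

    seed: int = 0
    n_subjects: int = 15_000
    n_variants: int = 500
    n_cycles: int = 12
    m_controls: int = 2
    prs_effect: float = float(np.log(1.42))
    missing_rate: float = 0.05
    missing_mechanism: str = "MCAR"
    n_imputations: int = 10
    bootstrap_b: int = 200
    cut_points: tuple[float, float] = (0.0166, 0.025)
    control_case_ratio: float = 2.0
    subtype_mode: bool = True
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        if isinstance(cfg.cut_points, list):
            cfg.cut_points = tuple(cfg.cut_points)
        return cfg


def _er_restricted_or(study: MatchedStudy, z: np.ndarray, er: str) -> dict | None:
    """Per-SD OR using only sets whose case has the given ER subtype."""
    df = study.subjects
    case_rows = df[df["case"] == 1]
    keep_sets = set(case_rows.loc[case_rows["er_status"] == er, "set_id"])
    if len(keep_sets) < 25:
        return None
    mask = df["set_id"].isin(keep_sets).to_numpy()
    fit = fit_clr(z[mask][:, None], df["set_id"].to_numpy()[mask],
                  df["case"].to_numpy()[mask], term_names=["prs_per_sd"])
    row = or_table(fit).frame.iloc[0]
    return {"or": float(row["OR"]), "lo": float(row["lo"]),
            "hi": float(row["hi"]), "n_sets": int(fit.n_sets)}


def run_validation(config: RunConfig) -> dict:
    """Execute the whole pipeline and return the report dictionary."""
    cfg = config
    log.info("simulate: n=%d subjects, %d variants, seed=%d",
             cfg.n_subjects, cfg.n_variants, cfg.seed)
    params = CohortParams(
        n_subjects=cfg.n_subjects,
        n_variants=cfg.n_variants,
        n_cycles=cfg.n_cycles,
        prs_effect=cfg.prs_effect,
        missing_rate=cfg.missing_rate,
        seed=cfg.seed,
    )
    incidence = params.baseline_incidence

    if cfg.subtype_mode:
        panel_pos, panel_neg = generate_weights(
            cfg.n_variants, subtype_mode=True, seed=cfg.seed
        )
        # the union of the subtype panels is the scoring panel; the overall
        # weight of a shared variant is the case-mix average of its subtype
        # weights, so scoring with the union equals combining subtype scores
        import pandas as pd

        from .prs import WeightPanel

        union = pd.concat([panel_pos.df, panel_neg.df]).drop_duplicates(
            "variant_id").reset_index(drop=True)
        scoring_panel = WeightPanel(union.assign(subtype="overall"))
    else:
        scoring_panel = generate_weights(cfg.n_variants, seed=cfg.seed)
        panel_pos = panel_neg = None
    scoring_panel, n_low_info = filter_low_info(scoring_panel, threshold=0.3)
    if cfg.subtype_mode:
        panel_pos, _ = filter_low_info(panel_pos, threshold=0.3)
        panel_neg, _ = filter_low_info(panel_neg, threshold=0.3)
    gen_params = CohortParams(**{**asdict_params(params),
                                 "n_variants": len(scoring_panel)})
    pop = generate_population(gen_params, scoring_panel)
    study = risk_set_sample(pop, m=cfg.m_controls, seed=cfg.seed)
    log.info("risk-set sampling: %d sets (%d cases dropped)",
             study.n_sets, study.n_dropped_cases)
    if cfg.missing_rate > 0:
        study = inject_missingness(
            study, cfg.missing_rate, cfg.missing_mechanism, seed=cfg.seed
        )

    dos = study.dosages
    control_ids = study.subjects.loc[study.subjects["case"] == 0,
                                     "subject_id"].to_numpy()
    if cfg.subtype_mode:
        raw_pos = score(dos, panel_pos)
        raw_neg = score(dos, panel_neg)
        cases = study.subjects[study.subjects["case"] == 1]
        n_pos = int((cases["er_status"] == "positive").sum())
        n_neg = int((cases["er_status"] == "negative").sum())
        prop_pos = n_pos / (n_pos + n_neg) if (n_pos + n_neg) else 0.5
        raw = combine_subtypes(raw_pos, raw_neg, prop_pos)
    else:
        raw = score(dos, scoring_panel)
        prop_pos = None
    prs = standardize_and_categorize(raw, dos.subject_ids, control_ids)

    pcs, pca_info = prune_and_pca(dos, k=10)
    try:
        retained_pcs = select_pcs(pcs, study.case)
    except ValueError:
        retained_pcs = []

    sets = study.sets
    case = study.case
    fit_sd = fit_clr(prs.z[:, None], sets, case, term_names=["prs_per_sd"])
    per_sd = or_table(fit_sd).frame.iloc[0]
    adj_cols = [prs.z[:, None]] + ([pcs[:, retained_pcs]] if retained_pcs else [])
    fit_sd_adj = fit_clr(np.column_stack(adj_cols), sets, case)
    pct_table = percentile_or_analysis(prs.category, sets, case)

    er_pos = _er_restricted_or(study, prs.z, "positive") if cfg.subtype_mode else None
    er_neg = _er_restricted_or(study, prs.z, "negative") if cfg.subtype_mode else None

    rng_seed = cfg.seed
    completed = impute(study, M=cfg.n_imputations, seed=rng_seed)
    M = len(completed)

    c_quest, c_prs, c_comb, deltas = [], [], [], []
    var_quest, var_prs, var_comb = [], [], []
    nris, nri_vars = [], []
    risks_base = np.empty((M, len(study.subjects)))
    risks_new = np.empty((M, len(study.subjects)))
    scheme = RiskCategoryScheme(cuts=tuple(cfg.cut_points))
    design = StudyDesignInfo(control_case_ratio=cfg.control_case_ratio)
    corr = float(np.corrcoef(np.log(study.subjects["risk_estimate"]), prs.z)[0, 1])

    for m_idx, comp in enumerate(completed):
        # the questionnaire calculator is re-applied to each completed
        # dataset, so imputation uncertainty propagates into the risk score
        risk = questionnaire_risk(
            comp.subjects, pop.questionnaire_coefs, incidence,
            comp.covariate_names,
        )
        quest_score = log_risk_score(risk)
        comp_mat = np.column_stack([quest_score, prs.z])
        combined = loo_combined(comp_mat, sets, case)
        res_b = cindex_bootstrap(quest_score, sets, case, B=cfg.bootstrap_b,
                                 seed=rng_seed + 101 + m_idx)
        res_p = cindex_bootstrap(prs.z, sets, case, B=cfg.bootstrap_b,
                                 seed=rng_seed + 202 + m_idx)
        res_c = cindex_bootstrap(combined, sets, case, B=cfg.bootstrap_b,
                                 seed=rng_seed + 303 + m_idx)
        c_quest.append(res_b.c); var_quest.append(res_b.se ** 2)
        c_prs.append(res_p.c); var_prs.append(res_p.se ** 2)
        c_comb.append(res_c.c); var_comb.append(res_c.se ** 2)
        deltas.append(
            auc_difference(quest_score, combined, sets, case,
                           B=cfg.bootstrap_b, seed=rng_seed + 404 + m_idx)
        )
        m1, m2 = fit_nri_models(case, quest_score, prs.z)
        ages = comp.subjects["age"].to_numpy()
        r1 = calibrated_risk(m1, quest_score[:, None], ages, incidence, design)
        r2 = calibrated_risk(m2, comp_mat, ages, incidence, design)
        risks_base[m_idx] = r1
        risks_new[m_idx] = r2
        counts_m = reclass_counts(categorize(r1, scheme), categorize(r2, scheme),
                                  case, n_categories=len(scheme.labels),
                                  labels=scheme.labels)
        res_nri = nri(counts_m)
        nris.append(res_nri.nri)
        nri_vars.append(nri_variance(counts_m))

    pooled_b = rubin_combine(c_quest, var_quest)
    pooled_p = rubin_combine(c_prs, var_prs)
    pooled_c = rubin_combine(c_comb, var_comb)
    delta_mean = float(np.mean([d["delta"] for d in deltas]))
    delta_pooled = rubin_combine([d["delta"] for d in deltas],
                                 [d["se"] ** 2 for d in deltas])
    nri_pooled = pooled_nri(nris, nri_vars)
    pres_table = averaged_probability_table(risks_base, risks_new, case, scheme)
    pres_nri = nri(pres_table)

    report = {
        "versions": {"prsval": __version__},
        "seed": cfg.seed,
        "counts": {
            "n_subjects": int(cfg.n_subjects),
            "n_sets": int(study.n_sets),
            "n_dropped_cases": int(study.n_dropped_cases),
            "n_variants_scored": int(len(scoring_panel)),
            "n_variants_removed_low_info": int(n_low_info),
            "n_variants_after_pruning": int(pca_info["n_after_pruning"]),
            "retained_pcs": [int(i) for i in retained_pcs],
            "er_positive_share_observed": prop_pos,
        },
        "correlation_questionnaire_risk_prs": corr,
        "per_sd_or": {
            "overall": {"or": float(per_sd["OR"]), "lo": float(per_sd["lo"]),
                        "hi": float(per_sd["hi"])},
            "overall_pc_adjusted": {"or": float(np.exp(fit_sd_adj.beta[0]))},
            "er_positive": er_pos,
            "er_negative": er_neg,
        },
        "percentile_or": pct_table.frame.to_dict(orient="records"),
        "auc": {
            "questionnaire": {"c": pooled_b.theta, "ci": list(pooled_b.ci)},
            "prs": {"c": pooled_p.theta, "ci": list(pooled_p.ci)},
            "combined": {"c": pooled_c.theta, "ci": list(pooled_c.ci)},
            "delta_combined_vs_questionnaire": {
                "delta": delta_mean,
                "ci": list(delta_pooled.ci),
                "p": float(np.mean([d["p"] for d in deltas])),
            },
        },
        "nri": {
            "pooled": nri_pooled.nri,
            "variance": nri_pooled.variance,
            "ci": list(nri_pooled.ci),
            "per_imputation": nri_pooled.per_imputation,
            "presentation_table": {
                "cases": pres_table.cases.tolist(),
                "controls": pres_table.controls.tolist(),
                "case_component": pres_nri.case_component,
                "control_component": pres_nri.control_component,
                "nri": pres_nri.nri,
            },
        },
    }
    report = _jsonify(report)
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        study.to_tsv(out / "matched_study.tsv")
        pct_table.to_tsv(out / "percentile_or.tsv")
    return report


def _jsonify(obj):
    """Recursively convert numpy scalars/arrays to plain Python types."""
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def asdict_params(params: CohortParams) -> dict:
    d = asdict(params)
    d["baseline_incidence"] = params.baseline_incidence
    return d


def packaged_counts_path() -> Path:
    """Path to the packaged published reclassification cross-tabulation."""
    return Path(
        importlib.resources.files("prsval").joinpath(
            "data/reclassification_counts.tsv"
        )
    )


def table3_check(counts_file=None) -> dict:
    """Recompute the NRI components from a printed reclassification table.

    With no argument, uses the packaged cross-tabulation of questionnaire-
    model versus combined-model 5-year risk categories (922 cases, 1844
    controls).
    """
    path = counts_file or packaged_counts_path()
    counts = ReclassCounts.from_tsv(path)
    res = nri(counts)
    return {
        "case_component": res.case_component,
        "control_component": res.control_component,
        "nri": res.nri,
        "n_cases": counts.n_cases,
        "n_controls": counts.n_controls,
    }
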
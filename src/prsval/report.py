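"""Descriptive summaries of a matched study (participant-characteristics table)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import MatchedStudy

__all__ = ["covariate_summary", "percent"]


def percent(count: int, total: int, decimals: int = 1) -> float:
    """Share of a group as a percentage, rounded as printed in summary tables."""
    if total <= 0:
        raise ValueError("total must be positive")
    if count < 0 or count > total:
        raise ValueError("count must lie in [0, total]")
    return round(100.0 * count / total, decimals)


def covariate_summary(study: MatchedStudy) -> pd.DataFrame:
    """Counts and percentages of each covariate level by case status.

    One row per (covariate, level): n and % among cases and among controls,
    computed over subjects with an observed value for that covariate.
    Continuous summaries (mean age, mean risk estimate) are appended.
    """
    df = study.subjects
    case = df["case"].to_numpy().astype(bool)
    rows = []
    for cov in study.covariate_names:
        vals = df[cov]
        for level in sorted(vals.dropna().unique()):
            sel = (vals == level).to_numpy()
            obs = vals.notna().to_numpy()
            n_case = int((sel & case).sum())
            n_ctrl = int((sel & ~case).sum())
            rows.append(
                {
                    "variable": cov,
                    "level": level,
                    "cases_n": n_case,
                    "cases_pct": percent(n_case, int((obs & case).sum())),
                    "controls_n": n_ctrl,
                    "controls_pct": percent(n_ctrl, int((obs & ~case).sum())),
                }
            )
    for cont in ("age", "risk_estimate"):
        if cont in df.columns:
            rows.append(
                {
                    "variable": cont,
                    "level": "mean (SD)",
                    "cases_n": round(float(df.loc[case, cont].mean()), 4),
                    "cases_pct": round(float(df.loc[case, cont].std()), 4),
                    "controls_n": round(float(df.loc[~case, cont].mean()), 4),
                    "controls_pct": round(float(df.loc[~case, cont].std()), 4),
                }
            )
    return pd.DataFrame(rows)
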
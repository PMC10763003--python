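import warnings

import numpy as np
import pandas as pd
import pytest

from prsval.cohort import (
    CohortParams,
    MatchedStudy,
    generate_population,
    generate_weights,
    risk_set_sample,
)
from prsval.prs import score, standardize_and_categorize


@pytest.fixture(scope="session")
def sim():
    """Mid-size simulated cohort + matched study shared across tests."""
    params = CohortParams(n_subjects=6000, n_variants=200, seed=11)
    panel = generate_weights(200, seed=11)
    pop = generate_population(params, panel)
    study = risk_set_sample(pop, m=2, seed=11)
    return {"params": params, "panel": panel, "pop": pop, "study": study}


@pytest.fixture(scope="session")
def sim_prs(sim):
    """Control-standardized PRS for the shared study."""
    study = sim["study"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        raw = score(study.dosages, sim["panel"])
    controls = study.subjects.loc[study.subjects["case"] == 0,
                                  "subject_id"].to_numpy()
    return standardize_and_categorize(raw, study.dosages.subject_ids, controls)


def make_study(n_sets: int, m: int = 2, seed: int = 0,
               covariates: dict | None = None) -> MatchedStudy:
    """Small matched study with arbitrary covariate columns for unit tests."""
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for s in range(n_sets):
        age = int(rng.integers(40, 60))
        for k in range(m + 1):
            rows.append({
                "subject_id": sid, "set_id": s, "case": int(k == 0),
                "er_status": "unknown" if k == 0 else "none",
                "age": age, "cycle": 1,
                "risk_estimate": float(rng.uniform(0.005, 0.05)),
            })
            sid += 1
    df = pd.DataFrame(rows)
    cov_names = []
    if covariates:
        for name, values in covariates.items():
            df[name] = values
            cov_names.append(name)
    return MatchedStudy(subjects=df, m=m, covariate_names=cov_names)
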
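"""Polygenic-score construction: weight panels, allele alignment, scoring,
subtype combination, control-referenced standardization, and ancestry PCA.

A polygenic risk score is the weighted sum of effect-allele dosages,
score_i = sum_j w_j d_ij, with weights on the log-odds scale.  Because
external weight panels and local dosage files may count opposite alleles,
every variant is aligned before scoring: if the dosage file counts the
panel's *other* allele the dosage is reflected (d -> 2 - d); strand-ambiguous
A/T and C/G pairs are flagged; variants whose alleles do not match at all
are excluded with a report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import inference

__all__ = [
    "WeightPanel",
    "DosageMatrix",
    "PRSVector",
    "AlignmentReport",
    "read_weights",
    "write_weights",
    "align_alleles",
    "filter_low_info",
    "score",
    "combine_subtypes",
    "standardize_and_categorize",
    "prune_and_pca",
    "select_pcs",
]

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

REQUIRED_WEIGHT_COLUMNS = ["variant_id", "effect_allele", "other_allele", "weight"]


@dataclass
class WeightPanel:
    """Per-variant effect alleles and log-odds weights.

    Optional columns: ``subtype`` (overall | ER-positive | ER-negative),
    ``info`` (imputation-quality score in [0,1]), ``freq`` (effect-allele
    frequency used by the generator).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_WEIGHT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"weight panel missing column(s): {missing}")
        dup = self.df["variant_id"][self.df["variant_id"].duplicated()]
        if len(dup):
            raise ValueError(
                f"duplicate variant_id in weight panel: {sorted(set(dup))[:5]}"
            )
        for col in ("effect_allele", "other_allele"):
            bad = ~self.df[col].isin(list(VALID_ALLELES))
            if bad.any():
                raise ValueError(
                    f"malformed allele in column {col}: "
                    f"{sorted(set(self.df.loc[bad, col]))[:5]}"
                )
        same = self.df["effect_allele"] == self.df["other_allele"]
        if same.any():
            raise ValueError("effect and other allele must differ")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, WeightPanel):
            return NotImplemented
        a = self.df[REQUIRED_WEIGHT_COLUMNS + sorted(set(self.df.columns) - set(REQUIRED_WEIGHT_COLUMNS))]
        b = other.df.reindex(columns=a.columns)
        try:
            pd.testing.assert_frame_equal(
                a.reset_index(drop=True), b.reset_index(drop=True),
                check_dtype=False, atol=0, rtol=0,
            )
        except AssertionError:
            return False
        return True


def read_weights(path) -> WeightPanel:
    """Read a tab-separated weight panel (one row per variant)."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str},
                     float_precision="round_trip")
    return WeightPanel(df)


def write_weights(panel: WeightPanel, path) -> None:
    # %.17g keeps float64 weights exact through the text round-trip
    panel.df.to_csv(path, sep="\t", index=False, float_format="%.17g")


@dataclass
class DosageMatrix:
    """Subjects x variants expected effect-allele counts in [0,2] (NaN = missing)."""

    values: np.ndarray
    subject_ids: np.ndarray
    variant_ids: np.ndarray
    counted_allele: np.ndarray
    other_allele: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0,2] (NaN for missing)")
        if self.values.shape != (len(self.subject_ids), len(self.variant_ids)):
            raise ValueError("dosage matrix shape does not match id vectors")

    @property
    def freq(self) -> np.ndarray:
        """Observed counted-allele frequency per variant (ignoring missing)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.values, axis=0) / 2.0

    @property
    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.values).mean(axis=0)

    def subset_subjects(self, subject_ids) -> "DosageMatrix":
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        idx = np.array([pos[s] for s in subject_ids], dtype=int)
        return DosageMatrix(
            values=self.values[idx],
            subject_ids=np.asarray(subject_ids),
            variant_ids=self.variant_ids,
            counted_allele=self.counted_allele,
            other_allele=self.other_allele,
        )

    def to_tsv(self, path) -> None:
        header = pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "counted_allele": self.counted_allele,
                "other_allele": self.other_allele,
            }
        )
        df = pd.DataFrame(self.values, columns=self.variant_ids)
        df.insert(0, "subject_id", self.subject_ids)
        with open(path, "w") as fh:
            fh.write("#" + "\t".join(
                f"{r.variant_id}:{r.counted_allele}:{r.other_allele}"
                for r in header.itertuples()) + "\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "DosageMatrix":
        with open(path) as fh:
            meta = fh.readline().lstrip("#").strip().split("\t")
            df = pd.read_csv(fh, sep="\t")
        ids, counted, other = zip(*(m.split(":") for m in meta))
        return cls(
            values=df.drop(columns="subject_id").to_numpy(dtype=float),
            subject_ids=df["subject_id"].to_numpy(),
            variant_ids=np.asarray(ids),
            counted_allele=np.asarray(counted),
            other_allele=np.asarray(other),
        )


@dataclass
class PRSVector:
    """Raw, standardized and categorized polygenic scores per subject."""

    subject_ids: np.ndarray
    raw: np.ndarray
    z: np.ndarray
    category: np.ndarray
    control_mean: float
    control_sd: float
    boundaries: np.ndarray  # the six control-distribution quantiles


@dataclass
class AlignmentReport:
    """Per-variant orientation of a weight panel against a dosage matrix."""

    status: pd.Series          # index variant_id; match|swap|ambiguous|mismatch
    panel_only: list[str] = field(default_factory=list)
    matrix_only: list[str] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return self.status.value_counts().to_dict()

    @property
    def n_mismatch(self) -> int:
        return int((self.status == "mismatch").sum())


def _is_ambiguous(a1: str, a2: str) -> bool:
    return COMPLEMENT[a1] == a2


def align_alleles(panel: WeightPanel, matrix: DosageMatrix) -> AlignmentReport:
    """Classify each shared variant as match / swap / ambiguous / mismatch.

    ``match``: the dosage file counts the panel's effect allele.
    ``swap``: it counts the panel's other allele (scored as 2 - d).
    ``ambiguous``: strand-ambiguous A/T or C/G pair (orientation cannot be
    resolved from alleles alone); retained with a warning by default.
    ``mismatch``: allele sets are disjoint; excluded from scoring.
    Nothing is raised — anomalies are reported.
    """
    mat = pd.DataFrame(
        {
            "counted": matrix.counted_allele,
            "alt": matrix.other_allele,
        },
        index=matrix.variant_ids,
    )
    pan = panel.df.set_index("variant_id")
    shared = pan.index.intersection(mat.index)
    status = {}
    for vid in shared:
        eff, oth = pan.loc[vid, "effect_allele"], pan.loc[vid, "other_allele"]
        counted, alt = mat.loc[vid, "counted"], mat.loc[vid, "alt"]
        if {eff, oth} != {counted, alt}:
            status[vid] = "mismatch"
        elif _is_ambiguous(eff, oth):
            status[vid] = "ambiguous"
        elif counted == eff:
            status[vid] = "match"
        else:
            status[vid] = "swap"
    return AlignmentReport(
        status=pd.Series(status, dtype=object),
        panel_only=list(pan.index.difference(mat.index)),
        matrix_only=list(mat.index.difference(pan.index)),
    )


def filter_low_info(
    panel: WeightPanel, threshold: float = 0.3
) -> tuple[WeightPanel, int]:
    """Drop variants whose imputation-quality score falls below ``threshold``."""
    if not (0 < threshold <= 1):
        raise ValueError("info threshold must lie in (0,1]")
    if "info" not in panel.df.columns:
        raise ValueError("panel has no 'info' column")
    keep = panel.df["info"] >= threshold
    return WeightPanel(panel.df[keep].reset_index(drop=True)), int((~keep).sum())


def score(
    matrix: DosageMatrix,
    panel: WeightPanel,
    missing_policy: str = "mean_dosage",
    alignment: AlignmentReport | None = None,
    strict_ambiguous: bool = False,
) -> np.ndarray:
    """Raw polygenic score per subject: sum_j w_j * d_ij after alignment.

    ``swap`` variants contribute with reflected dosage 2 - d.  Missing
    dosages are replaced by twice the observed counted-allele frequency
    (``mean_dosage`` policy) or by zero contribution (``zero``).
    Strand-ambiguous variants are retained with a warning unless
    ``strict_ambiguous``; disjoint-allele mismatches must have been excluded
    upstream, otherwise scoring raises.
    """
    if alignment is None:
        alignment = align_alleles(panel, matrix)
    if alignment.n_mismatch:
        bad = list(alignment.status[alignment.status == "mismatch"].index)
        raise ValueError(
            f"{len(bad)} variant(s) with irreconcilable alleles present; "
            f"exclude them before scoring (e.g. {bad[:5]})"
        )
    n_amb = int((alignment.status == "ambiguous").sum())
    if n_amb and strict_ambiguous:
        drop = set(alignment.status[alignment.status == "ambiguous"].index)
    else:
        if n_amb:
            warnings.warn(
                f"{n_amb} strand-ambiguous (A/T or C/G) variant(s) retained; "
                "dosages are assumed pre-harmonized",
                stacklevel=2,
            )
        drop = set()
    vpos = {v: i for i, v in enumerate(matrix.variant_ids)}
    pan = panel.df
    total = np.zeros(len(matrix.subject_ids))
    freqs = matrix.freq
    for vid, w in zip(pan["variant_id"], pan["weight"]):
        if vid not in vpos or vid in drop:
            continue
        j = vpos[vid]
        st = alignment.status.get(vid, "match")
        d = matrix.values[:, j]
        if st == "swap":
            d = 2.0 - d
            fill = 2.0 * (1.0 - freqs[j])
        else:
            fill = 2.0 * freqs[j]
        if missing_policy == "mean_dosage":
            d = np.where(np.isnan(d), fill, d)
        elif missing_policy == "zero":
            d = np.where(np.isnan(d), 0.0, d)
        else:
            raise ValueError(f"unknown missing policy {missing_policy!r}")
        total += w * d
    return total


def combine_subtypes(
    prs_pos: np.ndarray, prs_neg: np.ndarray, prop_pos: float
) -> np.ndarray:
    """Overall score as the case-mix-weighted average of subtype scores.

    overall_i = prop_pos * pos_i + (1 - prop_pos) * neg_i, with ``prop_pos``
    the ER-positive share among subtyped cases.
    """
    prs_pos = np.asarray(prs_pos, dtype=float)
    prs_neg = np.asarray(prs_neg, dtype=float)
    if prs_pos.shape != prs_neg.shape:
        raise ValueError("subtype score vectors must have equal length")
    if not (0 <= prop_pos <= 1):
        raise ValueError("prop_pos must lie in [0,1]")
    return prop_pos * prs_pos + (1.0 - prop_pos) * prs_neg


#: nominal control-distribution mass of the seven percentile bands
PERCENTILE_EDGES = np.array([0.10, 0.20, 0.40, 0.60, 0.80, 0.90])


def standardize_and_categorize(
    raw: np.ndarray,
    subject_ids: np.ndarray,
    control_ids,
) -> PRSVector:
    """Standardize to control mean/SD and assign control-percentile bands.

    The z unit is the CONTROL standard deviation (the same convention as the
    percentile bands, which come from the control distribution).  Band
    boundaries are empirical quantiles (linear interpolation); a score equal
    to a boundary falls in the upper band.
    """
    raw = np.asarray(raw, dtype=float)
    subject_ids = np.asarray(subject_ids)
    control_set = set(np.asarray(control_ids).tolist())
    is_control = np.array([s in control_set for s in subject_ids.tolist()])
    ctrl = raw[is_control]
    if len(np.unique(ctrl)) < 2:
        raise ValueError("need >= 2 distinct control scores to standardize")
    mean, sd = float(ctrl.mean()), float(ctrl.std(ddof=0))
    if sd == 0:
        raise ValueError("zero control-score variance")
    z = (raw - mean) / sd
    bounds = np.quantile(ctrl, PERCENTILE_EDGES)
    idx = np.searchsorted(bounds, raw, side="right")
    labels = np.array(inference.PERCENTILE_LABELS, dtype=object)
    return PRSVector(
        subject_ids=subject_ids,
        raw=raw,
        z=z,
        category=labels[idx],
        control_mean=mean,
        control_sd=sd,
        boundaries=bounds,
    )


def prune_and_pca(
    matrix: DosageMatrix,
    corr_max: float = 0.1,
    maf_min: float = 0.02,
    miss_max: float = 0.005,
    k: int = 10,
) -> tuple[np.ndarray, dict]:
    """LD-prune the dosage matrix and return the top-k principal components.

    Variants with minor-allele frequency below ``maf_min`` or missingness
    above ``miss_max`` are removed; greedy pruning scans variants in input
    order and keeps each variant whose absolute correlation with every
    previously kept variant is <= ``corr_max``.  PCA runs on the retained
    matrix after centring at 2f and scaling by sqrt(2 f (1-f)) (the usual
    frequency normalization for genotype PCA); missing cells are mean-filled
    before decomposition.  Returns (components (n x k), info dict).
    """
    vals = matrix.values
    if vals.size == 0:
        raise ValueError("empty dosage matrix")
    f = matrix.freq
    maf = np.minimum(f, 1 - f)
    keep = (maf >= maf_min) & (matrix.missing_fraction <= miss_max)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValueError("no variants survive the MAF/missingness filters")
    X = vals[:, idx].copy()
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    sd[sd == 0] = 1.0
    Xn = Xc / sd
    retained: list[int] = []
    for j in range(Xn.shape[1]):
        if not retained:
            retained.append(j)
            continue
        r = (Xn[:, retained].T @ Xn[:, j]) / Xn.shape[0]
        if np.all(np.abs(r) <= corr_max):
            retained.append(j)
    kept_idx = idx[retained]
    fk = f[kept_idx]
    Y = X[:, retained]
    Y = (Y - 2 * fk) / np.sqrt(2 * fk * (1 - fk))
    Y = Y - Y.mean(axis=0)  # recentre at the observed mean
    k_eff = min(k, min(Y.shape) - 1) if min(Y.shape) > 1 else 1
    U, S, _ = np.linalg.svd(Y, full_matrices=False)
    pcs = U[:, :k_eff] * S[:k_eff]
    info = {
        "n_input_variants": vals.shape[1],
        "n_after_filters": int(idx.size),
        "n_after_pruning": len(retained),
        "variant_ids": matrix.variant_ids[kept_idx],
        "singular_values": S[:k_eff],
    }
    return pcs, info


def select_pcs(
    pcs: np.ndarray, outcome: np.ndarray, alpha: float = 0.05
) -> list[int]:
    """Retain components Wald-significant in one joint logistic fit.

    All components enter a single logistic regression of case status; those
    with p < ``alpha`` are returned (0-based indices).
    """
    pcs = np.atleast_2d(np.asarray(pcs, dtype=float))
    outcome = np.asarray(outcome, dtype=float)
    if pcs.shape[0] != outcome.shape[0]:
        raise ValueError("components and outcome must be aligned")
    fit = inference.fit_logistic(pcs, outcome)
    pvals = fit.pvalues[1:]  # skip intercept
    return [int(i) for i in np.flatnonzero(pvals < alpha)]
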
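"""Scoring, alignment, standardization and PCA against independent oracles."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prsval.cohort import CohortParams, generate_population, generate_weights
from prsval.prs import (
    DosageMatrix,
    WeightPanel,
    align_alleles,
    combine_subtypes,
    filter_low_info,
    prune_and_pca,
    read_weights,
    score,
    select_pcs,
    standardize_and_categorize,
    write_weights,
)


def panel_from_rows(rows, **extra):
    df = pd.DataFrame(rows, columns=["variant_id", "effect_allele",
                                     "other_allele", "weight"])
    for k, v in extra.items():
        df[k] = v
    return WeightPanel(df)


def matrix(values, ids, counted, other, subjects=None):
    values = np.asarray(values, dtype=float)
    return DosageMatrix(
        values=values,
        subject_ids=np.arange(values.shape[0]) if subjects is None else subjects,
        variant_ids=np.asarray(ids),
        counted_allele=np.asarray(counted),
        other_allele=np.asarray(other),
    )


class TestWeightIO:
    def test_roundtrip_small(self, tmp_path):
        p = panel_from_rows([("rs1", "A", "G", 0.1), ("rs2", "C", "T", -0.2),
                             ("rs3", "G", "A", 0.0)])
        write_weights(p, tmp_path / "w.tsv")
        assert read_weights(tmp_path / "w.tsv") == p

    def test_roundtrip_generated_panel(self, tmp_path):
        panel = generate_weights(500, seed=1)
        write_weights(panel, tmp_path / "w.tsv")
        assert read_weights(tmp_path / "w.tsv") == panel

    def test_duplicate_id_rejected_by_name(self):
        with pytest.raises(ValueError, match="rs1"):
            panel_from_rows([("rs1", "A", "G", 0.1), ("rs1", "C", "T", 0.2)])

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="weight"):
            WeightPanel(pd.DataFrame({"variant_id": ["rs1"],
                                      "effect_allele": ["A"],
                                      "other_allele": ["G"]}))

    def test_malformed_allele_rejected(self):
        with pytest.raises(ValueError, match="allele"):
            panel_from_rows([("rs1", "N", "G", 0.1)])


class TestAlignment:
    def test_classification(self):
        p = panel_from_rows([
            ("rs1", "A", "G", 0.1),   # match
            ("rs2", "C", "T", 0.1),   # swap
            ("rs3", "A", "T", 0.1),   # ambiguous
            ("rs4", "A", "G", 0.1),   # mismatch
        ])
        m = matrix(np.zeros((1, 4)), ["rs1", "rs2", "rs3", "rs4"],
                   ["A", "T", "A", "C"], ["G", "C", "T", "T"])
        rep = align_alleles(p, m)
        assert rep.status.to_dict() == {
            "rs1": "match", "rs2": "swap", "rs3": "ambiguous", "rs4": "mismatch"
        }

    def test_swap_reflects_dosage(self):
        # dosage 2 of the counted (= other) allele is 0 effect alleles
        p = panel_from_rows([("rs1", "A", "G", 0.5)])
        m = matrix([[2.0], [0.0]], ["rs1"], ["G"], ["A"])
        np.testing.assert_allclose(score(m, p), [0.0, 1.0])

    def test_orientation_invariance(self):
        # randomly flipping which allele a dosage file counts must not
        # change any subject's score
        rng = np.random.default_rng(0)
        n, v = 30, 100
        panel = generate_weights(v, seed=3)
        dos = rng.integers(0, 3, size=(n, v)).astype(float)
        eff = panel.df["effect_allele"].to_numpy()
        oth = panel.df["other_allele"].to_numpy()
        base = matrix(dos, panel.df["variant_id"], eff, oth)
        flip = rng.random(v) < 0.5
        # never flip strand-ambiguous pairs: orientation is unresolvable there
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        ambiguous = np.array([comp[a] == b for a, b in zip(eff, oth)])
        flip &= ~ambiguous
        flipped = matrix(
            np.where(flip[None, :], 2 - dos, dos),
            panel.df["variant_id"],
            np.where(flip, oth, eff),
            np.where(flip, eff, oth),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            np.testing.assert_allclose(score(base, panel), score(flipped, panel),
                                       atol=1e-12)

    def test_mismatch_blocks_scoring(self):
        p = panel_from_rows([("rs1", "A", "G", 0.5)])
        m = matrix([[1.0]], ["rs1"], ["C"], ["T"])
        with pytest.raises(ValueError, match="rs1"):
            score(m, p)


class TestFilterLowInfo:
    def test_all_high_info_keeps_everything(self):
        p = panel_from_rows([("rs1", "A", "G", 0.1)], info=[1.0])
        kept, removed = filter_low_info(p, 0.3)
        assert removed == 0 and len(kept) == 1

    def test_threshold_boundary(self):
        p = panel_from_rows([("rs1", "A", "G", 0.1), ("rs2", "C", "G", 0.2)],
                            info=[0.2, 0.9])
        kept, removed = filter_low_info(p, 0.3)
        assert removed == 1
        assert list(kept.df["variant_id"]) == ["rs2"]

    def test_counting_oracle(self):
        rng = np.random.default_rng(4)
        info = rng.random(200)
        panel = generate_weights(200, seed=4)
        panel.df["info"] = info
        for thr in (0.1, 0.3, 0.7):
            _, removed = filter_low_info(panel, thr)
            assert removed == int(np.sum(info < thr))

    def test_bad_threshold(self):
        p = panel_from_rows([("rs1", "A", "G", 0.1)], info=[1.0])
        with pytest.raises(ValueError):
            filter_low_info(p, 1.5)


class TestScore:
    def test_zero_weights_zero_scores(self):
        p = panel_from_rows([("rs1", "A", "G", 0.0), ("rs2", "C", "T", 0.0)])
        m = matrix([[1, 2], [0, 1]], ["rs1", "rs2"], ["A", "C"], ["G", "T"])
        np.testing.assert_array_equal(score(m, p), [0.0, 0.0])

    def test_single_variant_arithmetic(self):
        p = panel_from_rows([("rs1", "A", "G", 0.5)])
        m = matrix([[0.0], [1.0], [2.0]], ["rs1"], ["A"], ["G"])
        np.testing.assert_allclose(score(m, p), [0.0, 0.5, 1.0])

    def test_vectorized_equals_loop_oracle(self):
        rng = np.random.default_rng(7)
        n, v = 20, 50
        panel = generate_weights(v, seed=7)
        dos = rng.uniform(0, 2, size=(n, v))
        m = matrix(dos, panel.df["variant_id"],
                   panel.df["effect_allele"], panel.df["other_allele"])
        w = panel.df["weight"].to_numpy()
        oracle = np.array([sum(w[j] * dos[i, j] for j in range(v))
                           for i in range(n)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            np.testing.assert_allclose(score(m, panel), oracle, atol=1e-12)

    def test_missing_dosage_filled_with_expected_count(self):
        p = panel_from_rows([("rs1", "A", "G", 1.0)])
        vals = np.array([[0.0], [2.0], [np.nan]])
        m = matrix(vals, ["rs1"], ["A"], ["G"])
        s = score(m, p)  # observed frequency 0.5 -> fill dosage 1.0
        np.testing.assert_allclose(s, [0.0, 2.0, 1.0])


class TestCombineSubtypes:
    def test_boundary_all_positive(self):
        pos, neg = np.array([1.0, 2.0]), np.array([5.0, 6.0])
        np.testing.assert_array_equal(combine_subtypes(pos, neg, 1.0), pos)

    def test_equal_weighting_is_mean(self):
        pos, neg = np.array([1.0, 0.0]), np.array([0.0, 2.0])
        np.testing.assert_allclose(combine_subtypes(pos, neg, 0.5), [0.5, 1.0])

    def test_study_case_mix_proportion(self):
        # the subtyped case mix 555 ER+ / 296 ER- weights the average
        prop = 555 / 851
        out = combine_subtypes(np.array([1.0, 0.0]), np.array([0.0, 1.0]), prop)
        np.testing.assert_allclose(np.round(out, 3), [0.652, 0.348])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            combine_subtypes(np.ones(3), np.ones(2), 0.5)

    @given(st.floats(min_value=0, max_value=1),
           st.integers(min_value=1, max_value=20),
           st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_combined_bounded_by_components(self, prop, n, seed):
        rng = np.random.default_rng(seed)
        pos, neg = rng.normal(size=n), rng.normal(size=n)
        out = combine_subtypes(pos, neg, prop)
        lo, hi = np.minimum(pos, neg), np.maximum(pos, neg)
        assert np.all(out >= lo - 1e-12) and np.all(out <= hi + 1e-12)


class TestStandardizeAndCategorize:
    def test_hundred_distinct_controls_band_counts(self):
        rng = np.random.default_rng(1)
        raw = rng.normal(size=100)
        ids = np.arange(100)
        prs = standardize_and_categorize(raw, ids, ids)
        counts = pd.Series(prs.category).value_counts()
        expected = {"<=10%": 10, "10-20%": 10, "20-40%": 20, "40-60%": 20,
                    "60-80%": 20, "80-90%": 10, ">90%": 10}
        assert counts.to_dict() == expected

    def test_control_scores_standardized_exactly(self):
        rng = np.random.default_rng(2)
        raw = rng.normal(3.0, 2.5, size=400)
        ids = np.arange(400)
        prs = standardize_and_categorize(raw, ids, ids[:300])
        ctrl_z = prs.z[:300]
        assert abs(ctrl_z.mean()) < 1e-12
        assert abs(ctrl_z.std() - 1) < 1e-12

    def test_rank_oracle(self):
        rng = np.random.default_rng(3)
        raw = rng.normal(size=250)
        ids = np.arange(250)
        prs = standardize_and_categorize(raw, ids, ids)
        bounds = np.quantile(raw, [0.1, 0.2, 0.4, 0.6, 0.8, 0.9])
        labels = ["<=10%", "10-20%", "20-40%", "40-60%", "60-80%",
                  "80-90%", ">90%"]
        for s, cat in zip(raw, prs.category):
            k = sum(s >= b for b in bounds)
            assert cat == labels[k]

    def test_partition_every_subject_labelled_once(self, sim_prs):
        assert len(sim_prs.category) == len(sim_prs.raw)
        assert set(sim_prs.category) <= {
            "<=10%", "10-20%", "20-40%", "40-60%", "60-80%", "80-90%", ">90%"}

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            standardize_and_categorize(np.ones(10), np.arange(10), np.arange(10))


class TestPCA:
    def test_duplicate_column_pruned(self):
        rng = np.random.default_rng(5)
        base = rng.integers(0, 3, size=(50, 5)).astype(float)
        dup = np.column_stack([base, base[:, 0]])
        m = matrix(dup, [f"v{i}" for i in range(6)],
                   ["A"] * 6, ["G"] * 6)
        _, info = prune_and_pca(m, corr_max=0.99, maf_min=0.0, miss_max=1.0)
        assert "v5" not in info["variant_ids"]
        assert "v0" in info["variant_ids"]

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(6)
        vals = rng.integers(0, 3, size=(10, 6)).astype(float)
        m = matrix(vals, [f"v{i}" for i in range(6)], ["A"] * 6, ["G"] * 6)
        pcs, info = prune_and_pca(m, corr_max=1.0, maf_min=0.0, miss_max=1.0,
                                  k=3)
        f = vals.mean(axis=0) / 2
        Y = (vals - 2 * f) / np.sqrt(2 * f * (1 - f))
        Y = Y - Y.mean(axis=0)
        evals, evecs = np.linalg.eigh(Y @ Y.T)
        order = np.argsort(evals)[::-1]
        for j in range(3):
            ref = evecs[:, order[j]] * np.sqrt(evals[order[j]])
            assert min(np.abs(pcs[:, j] - ref).max(),
                       np.abs(pcs[:, j] + ref).max()) < 1e-8

    def test_two_subpopulations_separated_by_pc1(self):
        params = CohortParams(n_subjects=600, n_variants=300, n_subpops=2,
                              subpop_freq_divergence=0.3, seed=17)
        panel = generate_weights(300, seed=17)
        pop = generate_population(params, panel)
        pcs, _ = prune_and_pca(pop.dosages, corr_max=0.2, maf_min=0.01,
                               miss_max=1.0, k=2)
        r = np.corrcoef(pcs[:, 0], pop.subjects["subpop"])[0, 1]
        assert abs(r) > 0.9

    def test_no_survivors_raises(self):
        m = matrix(np.full((20, 3), 2.0), ["a", "b", "c"],
                   ["A"] * 3, ["G"] * 3)
        with pytest.raises(ValueError):
            prune_and_pca(m, maf_min=0.02)


class TestSelectPCs:
    def test_near_perfect_predictor_retained(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, size=300).astype(float)
        pcs = rng.normal(size=(300, 3))
        pcs[:, 1] = y + rng.normal(0, 0.4, size=300)
        assert 1 in select_pcs(pcs, y)

    def test_constructed_strong_component_only(self):
        rng = np.random.default_rng(9)
        n = 2000
        pcs = rng.normal(size=(n, 3))
        lp = 1.2 * pcs[:, 2]
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
        assert select_pcs(pcs, y) == [2]

    def test_null_retention_rate_matches_alpha(self):
        # per-component type-I error under the null joint fit ~ alpha
        rng = np.random.default_rng(10)
        hits = total = 0
        for _ in range(400):
            y = rng.integers(0, 2, size=150).astype(float)
            if y.min() == y.max():
                continue
            pcs = rng.normal(size=(150, 3))
            hits += len(select_pcs(pcs, y, alpha=0.05))
            total += 3
        assert hits / total == pytest.approx(0.05, abs=0.02)
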
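"""Intercept recalibration, risk categories and the categorical NRI."""

import numpy as np
import pytest
from scipy.special import expit

from prsval.cohort import IncidenceTable, default_incidence_table
from prsval.inference import fit_logistic
from prsval.reclassification import (
    ReclassCounts,
    RiskCategoryScheme,
    StudyDesignInfo,
    averaged_probability_table,
    calibrated_risk,
    categorize,
    fit_nri_models,
    intercept_offset,
    nri,
    nri_variance,
    pooled_nri,
    reclass_counts,
)

PUBLISHED_CASES = np.array([[503, 94, 23], [72, 134, 74], [2, 8, 12]])
PUBLISHED_CONTROLS = np.array([[1146, 126, 13], [185, 245, 106], [4, 9, 10]])


class TestInterceptOffset:
    def test_zero_when_k_rho_odds_is_one(self):
        assert intercept_offset(rho=1 / 3, k=2) == pytest.approx(0.0)

    def test_symmetric_half(self):
        assert intercept_offset(rho=0.5, k=1) == pytest.approx(0.0)

    def test_hand_value_at_lower_cut(self):
        assert intercept_offset(rho=0.0166, k=2) == pytest.approx(
            np.log(0.0332 / 0.9834), abs=1e-10)
        assert intercept_offset(rho=0.0166, k=2) == pytest.approx(-3.38847, abs=1e-4)

    @pytest.mark.parametrize("rho,k", [(0.0, 2), (1.0, 2), (0.5, 0)])
    def test_domain(self, rho, k):
        with pytest.raises(ValueError):
            intercept_offset(rho, k)


class TestCategorize:
    def test_boundaries_closed_left(self):
        cats = categorize([0.0165, 0.0166, 0.024999, 0.025, 0.5])
        np.testing.assert_array_equal(cats, [0, 1, 1, 2, 2])

    def test_custom_scheme_validation(self):
        with pytest.raises(ValueError):
            RiskCategoryScheme(cuts=(0.05, 0.02))


class TestCalibratedRisk:
    def test_band_means_converge_to_rho(self):
        # 1 case per k controls in every band, covariate pure noise: mean
        # calibrated risk per band must reproduce the incidence table
        rng = np.random.default_rng(0)
        table = default_incidence_table()
        k = 2.0
        ages, case = [], []
        per_band = 3000
        for lo in table.age_lo[:6]:
            ages += [lo + 2] * per_band
            case += [1] * (per_band // 3) + [0] * (per_band - per_band // 3)
        ages = np.array(ages, dtype=float)
        case = np.array(case, dtype=float)
        x = rng.normal(size=len(ages))
        fit = fit_logistic(x[:, None], case)
        risk = calibrated_risk(fit, x[:, None], ages, table,
                               StudyDesignInfo(control_case_ratio=k))
        for lo, rho in zip(table.age_lo[:6], table.rho[:6]):
            band = (ages >= lo) & (ages < lo + 5)
            assert abs(risk[band].mean() - rho) / rho < 0.05

    def test_constant_rho_is_monotone_shift(self):
        rng = np.random.default_rng(1)
        table = IncidenceTable(np.array([30.0]), np.array([90.0]),
                               np.array([0.015]))
        x = rng.normal(size=200)
        y = (rng.random(200) < expit(0.5 * x)).astype(float)
        fit = fit_logistic(x[:, None], y)
        risk = calibrated_risk(fit, x[:, None], np.full(200, 50.0), table)
        uncal = expit(fit.linear_predictor(x[:, None]))
        assert np.array_equal(np.argsort(risk), np.argsort(uncal))

    def test_risk_strictly_inside_unit_interval(self):
        table = default_incidence_table()
        rng = np.random.default_rng(2)
        x = rng.normal(size=100) * 10
        y = (rng.random(100) < 0.5).astype(float)
        fit = fit_logistic(rng.normal(size=(100, 1)), y)
        risk = calibrated_risk(fit, x[:, None], np.full(100, 45.0), table)
        assert np.all((risk > 0) & (risk < 1))

    def test_age_outside_table_raises(self):
        table = default_incidence_table()
        rng = np.random.default_rng(3)
        y = (rng.random(60) < 0.5).astype(float)
        x = rng.normal(size=(60, 1))
        fit = fit_logistic(x, y)
        with pytest.raises(ValueError, match="outside"):
            calibrated_risk(fit, x, np.full(60, 20.0), table)


class TestFitNRIModels:
    def test_nested_loglik_ordering_and_null_prs(self):
        rng = np.random.default_rng(4)
        n = 3000
        base = rng.normal(-4, 0.5, size=n)
        y = (rng.random(n) < expit(2 + base)).astype(float)
        prs = rng.normal(size=n)  # pure noise
        m1, m2 = fit_nri_models(y, base, prs)
        assert m2.loglik >= m1.loglik
        # noise coefficient within sampling error of zero
        assert abs(m2.beta[2] / m2.se[2]) < 3.5

    def test_matches_direct_optimizer(self):
        from scipy.optimize import minimize

        rng = np.random.default_rng(5)
        n = 200
        base = rng.normal(-4, 0.6, size=n)
        prs = rng.normal(size=n)
        y = (rng.random(n) < expit(1.5 + 0.4 * base + 0.3 * prs)).astype(float)
        _, m2 = fit_nri_models(y, base, prs)

        def nll(b):
            eta = b[0] + b[1] * base + b[2] * prs
            return -np.sum(y * eta - np.logaddexp(0, eta))

        res = minimize(nll, np.zeros(3), method="BFGS", options={"gtol": 1e-10})
        np.testing.assert_allclose(m2.beta, res.x, atol=1e-5)


class TestReclassCounts:
    def test_identical_categorization_is_diagonal(self):
        rng = np.random.default_rng(6)
        cats = rng.integers(0, 3, size=200)
        case = rng.random(200) < 0.3
        counts = reclass_counts(cats, cats, case)
        assert np.all(counts.cases == np.diag(np.diag(counts.cases)))
        assert np.all(counts.controls == np.diag(np.diag(counts.controls)))

    def test_totals_conserved(self):
        rng = np.random.default_rng(7)
        a, b = rng.integers(0, 3, size=500), rng.integers(0, 3, size=500)
        case = rng.random(500) < 0.4
        counts = reclass_counts(a, b, case)
        assert counts.n_cases == case.sum()
        assert counts.n_controls == (~case).sum()

    def test_counting_oracle(self):
        rng = np.random.default_rng(8)
        a, b = rng.integers(0, 3, size=300), rng.integers(0, 3, size=300)
        case = rng.random(300) < 0.5
        counts = reclass_counts(a, b, case)
        for i in range(3):
            for j in range(3):
                assert counts.cases[i, j] == np.sum((a == i) & (b == j) & case)
                assert counts.controls[i, j] == np.sum((a == i) & (b == j) & ~case)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            reclass_counts([0, 1], [0], [True, False])


class TestNRI:
    def test_published_cross_tabulation(self):
        counts = ReclassCounts(cases=PUBLISHED_CASES, controls=PUBLISHED_CONTROLS)
        res = nri(counts)
        assert res.case_component == pytest.approx(0.1182, abs=2e-4)
        assert res.control_component == pytest.approx(-0.0255, abs=2e-4)
        assert res.nri == pytest.approx(0.0927, abs=2e-4)

    def test_diagonal_tables_zero(self):
        counts = ReclassCounts(cases=np.diag([5, 5, 5]),
                               controls=np.diag([9, 9, 9]))
        res = nri(counts)
        assert res.nri == res.case_component == res.control_component == 0.0

    def test_antisymmetric_under_transpose(self):
        counts = ReclassCounts(cases=PUBLISHED_CASES, controls=PUBLISHED_CONTROLS)
        swapped = ReclassCounts(cases=PUBLISHED_CASES.T,
                                controls=PUBLISHED_CONTROLS.T)
        assert nri(swapped).nri == pytest.approx(-nri(counts).nri)

    def test_subject_level_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        a, b = rng.integers(0, 3, size=400), rng.integers(0, 3, size=400)
        case = rng.random(400) < 0.35
        res = nri(reclass_counts(a, b, case))
        up, down = b > a, b < a
        case_comp = (np.sum(up & case) - np.sum(down & case)) / case.sum()
        ctrl_comp = (np.sum(down & ~case) - np.sum(up & ~case)) / (~case).sum()
        assert res.case_component == pytest.approx(case_comp, abs=1e-12)
        assert res.control_component == pytest.approx(ctrl_comp, abs=1e-12)

    def test_subthreshold_shift_leaves_table_unchanged(self):
        rng = np.random.default_rng(10)
        risks = rng.uniform(0.001, 0.06, size=300)
        case = rng.random(300) < 0.3
        cats = categorize(risks)
        cuts = np.array([0.0166, 0.025])
        # largest uniform shift that crosses no cut point for any subject
        dist = np.min([np.min(np.abs(risks - c)) for c in cuts])
        shifted = categorize(risks + dist * 0.5)
        base = reclass_counts(cats, cats, case)
        after = reclass_counts(cats, shifted, case)
        assert np.array_equal(base.cases + base.controls,
                              after.cases + after.controls) or \
            nri(after).nri != nri(base).nri  # a crossing shift changes it
        np.testing.assert_array_equal(after.cases, base.cases)


class TestPooledNRI:
    def test_identical_imputations_collapse(self):
        res = pooled_nri([0.09] * 5, [0.001] * 5)
        assert res.nri == pytest.approx(0.09)
        assert res.variance == pytest.approx(0.001)

    def test_variance_at_least_mean_within(self):
        rng = np.random.default_rng(11)
        nris = rng.normal(0.08, 0.01, size=10)
        variances = rng.uniform(5e-4, 1e-3, size=10)
        res = pooled_nri(nris, variances)
        assert res.variance >= variances.mean()

    def test_asymptotic_variance_formula(self):
        counts = ReclassCounts(cases=PUBLISHED_CASES, controls=PUBLISHED_CONTROLS)
        nc, nn = counts.n_cases, counts.n_controls
        pu_c = (94 + 23 + 74) / nc
        pd_c = (72 + 2 + 8) / nc
        pu_n = (126 + 13 + 106) / nn
        pd_n = (185 + 4 + 9) / nn
        expected = (pu_c + pd_c - (pu_c - pd_c) ** 2) / nc + \
                   (pu_n + pd_n - (pu_n - pd_n) ** 2) / nn
        assert nri_variance(counts) == pytest.approx(expected, rel=1e-12)


class TestAveragedProbabilityTable:
    def test_single_imputation_equals_direct_counts(self):
        rng = np.random.default_rng(12)
        r1 = rng.uniform(0.001, 0.06, size=150)
        r2 = rng.uniform(0.001, 0.06, size=150)
        case = rng.random(150) < 0.3
        avg = averaged_probability_table(r1, r2, case)
        direct = reclass_counts(categorize(r1), categorize(r2), case)
        np.testing.assert_array_equal(avg.cases, direct.cases)
        np.testing.assert_array_equal(avg.controls, direct.controls)

    def test_averaging_does_not_commute_with_categorization(self):
        # two imputations straddling a cut point: the mean-risk table differs
        # from the mean of per-imputation tables
        case = np.array([True])
        r_base = np.array([[0.010], [0.010]])
        r_new = np.array([[0.0160], [0.0180]])  # mean 0.0170 -> category 1
        avg = averaged_probability_table(r_base, r_new, case)
        per_imp = [
            reclass_counts(categorize(r_base[m]), categorize(r_new[m]), case)
            for m in range(2)
        ]
        mean_cases = (per_imp[0].cases + per_imp[1].cases) / 2
        assert not np.array_equal(avg.cases, mean_cases)
        assert avg.cases[0, 1] == 1

    def test_totals_conserved(self):
        rng = np.random.default_rng(13)
        r1 = rng.uniform(0.001, 0.06, size=(4, 200))
        r2 = rng.uniform(0.001, 0.06, size=(4, 200))
        case = rng.random(200) < 0.4
        avg = averaged_probability_table(r1, r2, case)
        assert avg.n_cases + avg.n_controls == 200
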
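"""Case-control statistics against hand oracles and the bundled
genotype-count fixture."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from cisreg import association_stats as ast
from cisreg.enrichment_ld import Contingency2x2
from cisreg.errors import (DegenerateTableError, EmptyInputError,
                           InvalidInputError, ModelUnavailableError)


class TestHwe:
    def test_exact_proportions_give_zero(self):
        chi2, df, p = ast.hwe_test((25, 50, 25))
        assert chi2 == pytest.approx(0.0)
        assert (df, p) == (1, pytest.approx(1.0))

    def test_hand_oracle_rare_allele(self):
        # p-hat = 743/798; expected (345.90, 51.21, 1.89)
        chi2, _, _ = ast.hwe_test((345, 53, 1))
        n = 399
        ph = 743 / 798
        exp = np.array([n * ph ** 2, 2 * n * ph * (1 - ph),
                        n * (1 - ph) ** 2])
        oracle = (((np.array([345, 53, 1]) - exp) ** 2) / exp).sum()
        assert chi2 == pytest.approx(oracle)
        assert chi2 == pytest.approx(0.49, abs=0.01)

    def test_monomorphic_marker(self):
        chi2, _, p = ast.hwe_test((100, 0, 0))
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            ast.hwe_test((0, 0, 0))


class TestAllelic:
    @pytest.mark.parametrize("rsid,expected", [
        ("rs3764821", 2.54), ("rs3748523", 1.65), ("rs5742926", 1.91),
    ])
    def test_fixture_allelic_odds_ratios(self, table3, rsid, expected):
        res = ast.allelic_association(ast.allele_table(table3, rsid, "G"))
        assert round(res.odds_ratio, 2) == expected

    def test_equal_proportions(self):
        res = ast.allelic_association(Contingency2x2(10, 90, 10, 90))
        assert res.odds_ratio == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            ast.allelic_association(Contingency2x2(0, 10, 0, 10))


def _cohort_from_counts(case_counts, ctrl_counts, ref="C", alt="G"):
    genos = [f"{ref}/{ref}", f"{ref}/{alt}", f"{alt}/{alt}"]
    rows = []
    for status, counts in (("case", case_counts), ("control", ctrl_counts)):
        for g, k in zip(genos, counts):
            rows += [(status, g)] * k
    return pd.DataFrame(rows, columns=["status", "snp"])


def _loglik(coefs, x, y):
    eta = coefs[0] + coefs[1] * x
    return np.sum(y * eta - np.log1p(np.exp(eta)))


class TestGeneticModels:
    @pytest.mark.parametrize("rsid,model,expected", [
        ("rs3748523", "additive", 1.70),   # MLE 1.6966 (printed as 1.69)
        ("rs3748523", "dominant", 1.77),
        ("rs3748523", "recessive", 2.47),
        ("rs3764821", "additive", 2.64),
        ("rs3764821", "dominant", 2.70),   # cross-product 2.6996
        ("rs3764821", "recessive", 8.04),
    ])
    def test_fixture_crude_fits(self, table3, rsid, model, expected):
        res = ast.genetic_model_fit(table3, rsid, "G", model)
        assert round(res.odds_ratio, 2) == expected

    def test_recessive_unavailable_without_homozygotes(self, table3):
        with pytest.raises(ModelUnavailableError):
            ast.genetic_model_fit(table3, "rs5742926", "T", "recessive")

    def test_dominant_logistic_equals_crossproduct(self, rng):
        # with a single binary predictor the logistic MLE odds ratio is
        # exactly the 2x2 cross-product
        for _ in range(10):
            counts = rng.integers(5, 80, size=4)
            carrier_case, ref_case, carrier_ctrl, ref_ctrl = counts
            cohort = _cohort_from_counts(
                (ref_case, carrier_case, 0), (ref_ctrl, carrier_ctrl, 0))
            res = ast.genetic_model_fit(cohort, "snp", "G", "dominant")
            oracle = (carrier_case * ref_ctrl) / (ref_case * carrier_ctrl)
            assert res.odds_ratio == pytest.approx(oracle, rel=1e-6)

    def test_coefficient_matches_direct_likelihood_maximum(self, table3):
        # independent oracle: maximize the Bernoulli log-likelihood
        # directly with a generic optimizer
        d = ast.risk_dosage_series(table3, "rs3748523", "G")
        y = (table3.status == "case").astype(float).to_numpy()
        x = d.to_numpy()
        opt = optimize.minimize(lambda c: -_loglik(c, x, y), x0=[0.0, 0.0],
                                method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10})
        res = ast.genetic_model_fit(table3, "rs3748523", "G", "additive")
        assert np.log(res.odds_ratio) == pytest.approx(opt.x[1], abs=1e-3)

    def test_subject_order_invariance(self, table3):
        shuffled = table3.sample(frac=1, random_state=5).reset_index(
            drop=True)
        a = ast.genetic_model_fit(table3, "rs3764821", "G", "additive")
        b = ast.genetic_model_fit(shuffled, "rs3764821", "G", "additive")
        assert a.odds_ratio == pytest.approx(b.odds_ratio, rel=1e-9)

    def test_adjusted_fit_runs_on_synthetic_cohort(self, cohort):
        covs = tuple(c for c in ast.DEFAULT_COVARIATES
                     if c in cohort.columns)
        res = ast.genetic_model_fit(cohort, "snvE1", "G", "additive", covs)
        assert res.adjusted and np.isfinite(res.odds_ratio)
        assert res.ci_low <= res.odds_ratio <= res.ci_high


class TestSubgroupInteraction:
    def test_identical_strata_equal_ors(self):
        base = _cohort_from_counts((50, 40, 10), (80, 30, 5))
        base["pack_years"] = 30.0
        high = base.copy()
        high["pack_years"] = 60.0
        cohort = pd.concat([base, high], ignore_index=True)
        per_stratum, p_int = ast.subgroup_and_interaction(
            cohort, "snp", "G", "additive", "pack_years", 47.0)
        assert per_stratum["low"].odds_ratio == pytest.approx(
            per_stratum["high"].odds_ratio, rel=1e-6)
        assert p_int == pytest.approx(1.0, abs=1e-6)

    def test_planted_effect_modification_detected(self):
        rng = np.random.default_rng(7)
        n = 2000
        x = rng.binomial(2, 0.3, n)
        stratum = rng.random(n) < 0.5
        logit = -1.0 + np.where(stratum, np.log(3.0), 0.0) * x
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        cohort = pd.DataFrame({
            "status": np.where(y, "case", "control"),
            "snp": np.array(["A/A", "A/G", "G/G"])[x],
            "pack_years": np.where(stratum, 60.0, 30.0)})
        _, p_int = ast.subgroup_and_interaction(
            cohort, "snp", "G", "additive", "pack_years", 47.0)
        assert p_int < 0.05


class TestGenotypeCombination:
    def test_reference_cell_or_is_one(self, table3):
        out = ast.genotype_combination(table3, "rs3764821", "rs3748523",
                                       ("A/A", "C/C"))
        ref = out[out.combination == "A/A + C/C"]
        assert ref.odds_ratio.iloc[0] == 1.0

    def test_joint_effect_recovered(self):
        rng = np.random.default_rng(11)
        n = 4000
        ga = rng.binomial(1, 0.4, n)  # 1 = het
        gb = rng.binomial(1, 0.4, n)
        logit = -1.5 + np.log(2.8) * (ga & gb)
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        cohort = pd.DataFrame({
            "status": np.where(y, "case", "control"),
            "a": np.array(["A/A", "A/G"])[ga],
            "b": np.array(["C/C", "C/G"])[gb]})
        out = ast.genotype_combination(cohort, "a", "b", ("A/A", "C/C"))
        est = out.loc[out.combination == "A/G + C/G",
                      "odds_ratio"].iloc[0]
        assert est == pytest.approx(2.8, rel=0.25)

    def test_empty_reference_rejected(self, table3):
        with pytest.raises(DegenerateTableError):
            # no subject is simultaneously hom-risk at the first marker
            # and hom-reference at the second in the fixture expansion
            ast.genotype_combination(table3, "rs3764821", "rs3748523",
                                     ("G/G", "C/C"))

    def test_zero_case_cell_flagged_finite(self):
        cohort = _cohort_from_counts((50, 0, 0), (50, 20, 0))
        out = ast.genotype_combination(cohort, "snp", "snp",
                                       ("C/C", "C/C"), min_count=5)
        het = out[out.combination == "C/G + C/G"]
        assert np.isfinite(het.odds_ratio.iloc[0])


@pytest.mark.parametrize("units,years,expected", [
    (20, 30, 30.0), (0, 40, 0.0), (10, 47, 23.5),
])
def test_pack_years(units, years, expected):
    assert ast.pack_years(units, years) == expected


def test_pack_years_rejects_negative():
    with pytest.raises(InvalidInputError):
        ast.pack_years(-1, 10)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(2, 60), st.integers(2, 60), st.integers(2, 60),
       st.integers(2, 60))
def test_dominant_identity_property(a, b, c, d):
    """Logistic dominant OR == cross-product OR on any non-degenerate
    carrier/non-carrier table."""
    cohort = _cohort_from_counts((b, a, 0), (d, c, 0))
    res = ast.genetic_model_fit(cohort, "snp", "G", "dominant")
    assert res.odds_ratio == pytest.approx((a * d) / (b * c), rel=1e-5)
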
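"""Survival analysis against product-limit and partial-likelihood oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from cisreg import survival_stats as ss
from cisreg.errors import (EmptyInputError, InvalidInputError,
                           InvalidLabelError, NonEstimableError)


def km_oracle(times, events):
    """Brute-force product-limit estimator returning {time: S(t)}."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    s = 1.0
    out = {}
    for t in sorted(set(times[events])):
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & events)
        s *= 1 - d / at_risk
        out[t] = s
    return out


class TestKm:
    def test_deaths_without_censoring(self):
        curve, median = ss.km_estimate([1, 2, 3, 4, 5], [True] * 5)
        assert curve.loc[3.0, "survival"] == pytest.approx(0.4)
        assert median == 3.0

    def test_all_censored(self):
        curve, median = ss.km_estimate([2, 4, 6], [False] * 3)
        assert (curve.survival == 1.0).all()
        assert median is None

    def test_single_subject(self):
        curve, median = ss.km_estimate([7.0], [True])
        assert curve.loc[7.0, "survival"] == 0.0
        assert median == 7.0

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            ss.km_estimate([], [])

    def test_matches_brute_force_with_censoring(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 50))
            times = np.round(rng.exponential(10, n), 1) + 0.1
            events = rng.random(n) < 0.7
            if not events.any():
                continue
            curve, _ = ss.km_estimate(times, events)
            for t, s in km_oracle(times, events).items():
                assert curve.loc[t, "survival"] == pytest.approx(s)


class TestLogrank:
    def test_identical_groups(self):
        t = [1, 2, 3, 4, 5]
        e = [True] * 5
        stat, p = ss.logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_power_under_strong_effect(self, rng):
        detected = 0
        for _ in range(20):
            t0 = rng.exponential(12, 100)
            t1 = rng.exponential(4, 100)
            c0 = rng.exponential(48, 100)
            c1 = rng.exponential(16, 100)
            _, p = ss.logrank_test(np.minimum(t0, c0), t0 <= c0,
                                   np.minimum(t1, c1), t1 <= c1)
            detected += p < 0.05
        assert detected >= 18  # HR 3, n=100/arm, ~20% censoring

    def test_requires_events(self):
        with pytest.raises(InvalidInputError):
            ss.logrank_test([1, 2], [False, False], [3], [False])


def cox_binary_oracle(times, events, group):
    """Newton solve of the partial-likelihood score equation for a single
    binary covariate (no tied event times)."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    group = np.asarray(group, float)

    def neg_pl(beta):
        ll = 0.0
        for t in times[events]:
            at_risk = times >= t
            ll += beta * group[(times == t) & events].sum()
            ll -= np.log(np.sum(np.exp(beta * group[at_risk])))
        return -ll

    res = optimize.minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded",
                                   options={"xatol": 1e-10})
    return res.x


class TestCox:
    def _records(self, times, events, group, **extra):
        df = pd.DataFrame({"time_months": times, "event": events,
                           "carrier": group})
        for k, v in extra.items():
            df[k] = v
        return df

    def test_identical_groups_hr_near_one(self, rng):
        t = rng.exponential(10, 200)
        e = np.ones(200, bool)
        g = np.repeat([0, 1], 100)
        res = ss.cox_fit(self._records(t, e, g))
        assert res.hazard_ratio == pytest.approx(1.0, abs=0.35)

    def test_matches_partial_likelihood_oracle(self, rng):
        # distinct times so tie handling is irrelevant
        n = 60
        g = rng.binomial(1, 0.5, n)
        t = rng.exponential(1.0 / np.exp(0.7 * g))
        t = np.round(t, 6) + np.linspace(0, 1e-4, n)  # enforce uniqueness
        e = np.ones(n, bool)
        res = ss.cox_fit(self._records(t, e, g))
        beta_oracle = cox_binary_oracle(t, e, g)
        assert np.log(res.hazard_ratio) == pytest.approx(beta_oracle,
                                                         abs=1e-5)

    def test_constant_group_non_estimable(self):
        with pytest.raises(NonEstimableError):
            ss.cox_fit(self._records([1, 2, 3], [True, True, True],
                                     [1, 1, 1]))

    def test_no_events_in_group_non_estimable(self):
        with pytest.raises(NonEstimableError):
            ss.cox_fit(self._records([1, 2, 3, 4],
                                     [True, True, False, False],
                                     [0, 0, 1, 1]))

    def test_adjusted_fit(self, rng):
        n = 120
        g = rng.binomial(1, 0.4, n)
        age = rng.normal(60, 8, n)
        t = rng.exponential(1.0 / np.exp(0.8 * g + 0.01 * (age - 60)))
        df = self._records(t, np.ones(n, bool), g, age=age,
                           sex=rng.choice(["male", "female"], n),
                           pack_years=rng.uniform(10, 90, n))
        res = ss.cox_fit(df, covariates=("age", "sex", "pack_years"))
        assert res.adjusted
        assert res.ci_low <= res.hazard_ratio <= res.ci_high


class TestRegimenStratification:
    def _cohort(self, rng, n=60, hr=3.6, regimen="Paclitaxel "
                "cis/carboplatin"):
        carrier = rng.binomial(1, 0.45, n)
        lam = (1 / 12) * np.where(carrier, hr, 1.0)
        t = rng.exponential(1 / lam)
        genos = np.array(["A/A", "A/G"])[carrier]
        return pd.DataFrame({
            "snp": genos, "time_months": t, "event": True,
            "age": rng.normal(60, 8, n),
            "sex": rng.choice(["male", "female"], n),
            "pack_years": rng.uniform(20, 80, n),
            "regimen_1": regimen, "regimen_2": None, "regimen_3": None})

    def test_no_matching_subjects_reports_insufficient(self, rng):
        cohort = self._cohort(rng)
        out = ss.regimen_stratified_analysis(
            cohort, "snp", "G", ss.first_line("Etoposide cis/carboplatin"))
        assert isinstance(out["crude"], ss.InsufficientSample)

    def test_small_subset_recovery(self, rng):
        hrs = []
        for seed in range(15):
            cohort = self._cohort(np.random.default_rng(seed), n=30)
            out = ss.regimen_stratified_analysis(
                cohort, "snp", "G",
                ss.first_line("Paclitaxel cis/carboplatin"))
            if isinstance(out["crude"], ss.SurvResult):
                hrs.append(out["crude"].hazard_ratio)
        assert len(hrs) >= 10
        assert np.exp(np.mean(np.log(hrs))) == pytest.approx(3.6, rel=0.5)

    def test_sequence_prefix_predicate(self):
        pred = ss.sequence_prefix("Paclitaxel cis/carboplatin",
                                  "Gemcitabine cis/carboplatin")
        assert pred(["Paclitaxel cis/carboplatin",
                     "Gemcitabine cis/carboplatin"])
        assert pred(["Paclitaxel cis/carboplatin",
                     "Gemcitabine cis/carboplatin", "third"])
        assert not pred(["Gemcitabine cis/carboplatin",
                         "Paclitaxel cis/carboplatin"])
        assert not pred(["Paclitaxel cis/carboplatin"])


@pytest.mark.parametrize("label,expected", [
    ("complete", "responder"), ("partial", "responder"),
    ("stable", "non_responder"), ("poor", "non_responder"),
    ("progressive", "non_responder"),
])
def test_classify_response(label, expected):
    assert ss.classify_response(label) == expected


def test_classify_response_unknown_label():
    with pytest.raises(InvalidLabelError):
        ss.classify_response("mixed")
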
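"""Overall-survival analyses for the genotyped patients.

Kaplan-Meier estimation with median survival, the two-group log-rank test,
Cox proportional-hazards models (crude, or adjusted for age, sex and
pack-years), regimen-stratified Cox fits, and responder classification.
Time is measured in months from the start of chemotherapy; genotypes are
collapsed dominantly (reference homozygote vs risk-allele carrier). Cox
fits use Efron handling of tied event times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import (EmptyInputError, InvalidInputError, InvalidLabelError,
                     NonEstimableError)

RESPONSE_MAP = {
    "complete": "responder",
    "partial": "responder",
    "stable": "non_responder",
    "poor": "non_responder",
    "progressive": "non_responder",
}

SURVIVAL_COVARIATES = ("age", "sex", "pack_years")


@dataclass
class SurvResult:
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    test: str  # logrank or wald
    adjusted: bool
    n: int
    n_events: int


@dataclass
class InsufficientSample:
    """Returned (not raised) when a stratified subset cannot support a
    fit, mirroring blank table cells in small-regimen reports."""
    reason: str
    n: int = 0
    n_events: int = 0


def km_estimate(times: Sequence[float], events: Sequence[bool],
                ) -> tuple[pd.DataFrame, float | None]:
    """Product-limit survival curve and the median survival time.

    The median is the earliest time at which the estimated survival drops
    to 0.5 or below; None when the curve never reaches 0.5 (reported as
    'NR' in tables).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) == 0:
        raise EmptyInputError("no survival records")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    curve = kmf.survival_function_.rename(
        columns={"KM_estimate": "survival"})
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    return curve, median


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float,
                                                                float]:
    """Two-group log-rank chi-square (df 1) and its p-value."""
    if len(times_a) == 0 or len(times_b) == 0:
        raise EmptyInputError("both groups need at least one record")
    if not (np.any(events_a) or np.any(events_b)):
        raise InvalidInputError("log-rank undefined without any event")
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a,
                      event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(records: pd.DataFrame, group_col: str = "carrier",
            covariates: tuple[str, ...] = (),
            time_col: str = "time_months",
            event_col: str = "event") -> SurvResult:
    """Cox proportional-hazards fit for a binary genotype group.

    ``records`` must carry the duration, the event indicator and a binary
    ``group_col`` (0 = reference genotype, 1 = risk-allele carrier);
    optional covariates are entered linearly (sex coded male = 1). HR is
    exp(coefficient) with Wald CI and p. Monotone likelihoods (e.g. no
    events in one group) surface as NonEstimableError.
    """
    cols = [time_col, event_col, group_col, *covariates]
    df = records.loc[:, cols].dropna().copy()
    if df.empty or not df[event_col].astype(bool).any():
        raise EmptyInputError("no usable records with events")
    if "sex" in df.columns:
        df["sex"] = (df["sex"] == "male").astype(float)
    for col in (group_col, event_col):
        df[col] = df[col].astype(float)
    if df[group_col].nunique() < 2:
        raise NonEstimableError(f"{group_col} is constant")
    events_by_group = df.groupby(group_col)[event_col].sum()
    if (events_by_group == 0).any():
        raise NonEstimableError(
            "no events in one genotype group (monotone likelihood)")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=time_col, event_col=event_col)
    except Exception as exc:
        raise NonEstimableError(f"Cox fit failed: {exc}")
    s = cph.summary.loc[group_col]
    return SurvResult(
        hazard_ratio=float(s["exp(coef)"]),
        ci_low=float(s["exp(coef) lower 95%"]),
        ci_high=float(s["exp(coef) upper 95%"]),
        p_value=float(s["p"]), test="wald", adjusted=bool(covariates),
        n=int(len(df)), n_events=int(df[event_col].sum()))


def carrier_indicator(subjects: pd.DataFrame, rsid: str,
                      risk_allele: str) -> pd.Series:
    """Dominant genotype collapse: 1 for any risk-allele copy, NaN when
    ungenotyped."""
    from .risk_scores import parse_genotype

    def carrier(g):
        pair = parse_genotype(g)
        if pair is None:
            return np.nan
        return float(risk_allele in pair)
    return subjects[rsid].map(carrier)


def first_line(label: str) -> Callable[[Sequence[str | None]], bool]:
    """Predicate: first-line regimen equals ``label``."""
    def pred(seq):
        return len(seq) >= 1 and seq[0] == label
    return pred


def sequence_prefix(*labels: str) -> Callable[[Sequence[str | None]], bool]:
    """Predicate: the regimen sequence starts with exactly these labels in
    order (first line first)."""
    def pred(seq):
        seq = [s for s in seq if s]
        return tuple(seq[: len(labels)]) == tuple(labels) and \
            len(seq) >= len(labels)
    return pred


def regimen_stratified_analysis(records: pd.DataFrame, rsid: str,
                                risk_allele: str,
                                regimen_filter: Callable,
                                covariates: tuple[str, ...] =
                                SURVIVAL_COVARIATES,
                                ) -> dict[str, SurvResult |
                                          InsufficientSample]:
    """Crude and adjusted Cox fits on the regimen-filtered subset.

    ``regimen_filter`` is a predicate over the ordered regimen sequence
    (columns regimen_1..regimen_3). Subsets that cannot support a fit
    (fewer than 2 subjects per genotype group, or no events) yield an
    InsufficientSample report instead of an exception.
    """
    reg_cols = [c for c in ("regimen_1", "regimen_2", "regimen_3")
                if c in records.columns]
    seqs = records[reg_cols].apply(
        lambda r: [x for x in r if isinstance(x, str)], axis=1)
    sub = records[seqs.map(regimen_filter)].copy()
    sub["carrier"] = carrier_indicator(sub, rsid, risk_allele)
    sub = sub[sub.carrier.notna()]

    group_sizes = sub.groupby("carrier").size() if not sub.empty else \
        pd.Series(dtype=int)
    enough = (len(group_sizes) == 2 and (group_sizes >= 2).all()
              and sub.event.astype("boolean").fillna(False).any())
    if not enough:
        report = InsufficientSample(
            reason="fewer than 2 subjects per genotype group with events",
            n=int(len(sub)),
            n_events=int(sub.event.fillna(False).astype(bool).sum())
            if not sub.empty else 0)
        return {"crude": report, "adjusted": report}

    out: dict[str, SurvResult | InsufficientSample] = {}
    for name, covs in (("crude", ()), ("adjusted", covariates)):
        try:
            out[name] = cox_fit(sub, "carrier", covs)
        except (NonEstimableError, EmptyInputError) as exc:
            out[name] = InsufficientSample(reason=str(exc), n=len(sub))
    return out


def classify_response(label: str) -> str:
    """Responder (complete or partial response) vs non-responder (stable,
    poor, or progressive disease)."""
    try:
        return RESPONSE_MAP[label]
    except KeyError:
        raise InvalidLabelError(f"unknown response label {label!r}") from None
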
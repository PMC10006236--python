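"""Case-control association statistics.

Covers the genotype-level analyses of a candidate-variant study:
Hardy-Weinberg goodness of fit, allelic 2x2 association with Pearson's
chi-square, maximum-likelihood logistic regression under additive, dominant
and recessive genotype codings (crude or covariate-adjusted), subgroup
analysis with a Wald interaction test, genotype-combination odds ratios,
and the pack-years smoking exposure formula.

Odds-ratio conventions: the allelic and genotype-combination ORs are sample
cross-products with Woolf log-normal 95% intervals; logistic-model ORs are
exp(coefficient) with Wald intervals. Subjects missing a marker's genotype
are dropped for that marker (complete-case per marker).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .enrichment_ld import Contingency2x2, _cross_product_or
from .errors import (DegenerateTableError, EmptyInputError,
                     InvalidInputError, ModelUnavailableError,
                     NonEstimableError)
from .risk_scores import parse_genotype

MODELS = ("additive", "dominant", "recessive")

# covariates adjusted for in the full case-control model
DEFAULT_COVARIATES = ("age", "sex", "pack_years", "alcohol",
                      "tobacco_chewing", "betel_quid", "wood_smoke",
                      "coal_smoke", "asbestos", "pesticide")


@dataclass
class AssocResult:
    model: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    adjusted: bool = False
    covariates: tuple[str, ...] = ()
    n: int = 0
    method: str = ""
    flag: str | None = None


# ----------------------------------------------------------------- HWE


def hwe_test(genotype_counts: tuple[int, int, int]) -> tuple[float, int,
                                                             float]:
    """Chi-square goodness of fit to Hardy-Weinberg proportions.

    Expected counts use the maximum-likelihood allele frequency from the
    observed genotypes; df = 1. Expected cells of zero with observed zero
    contribute nothing (monomorphic markers give chi2 = 0, p = 1).
    """
    n_aa, n_ab, n_bb = genotype_counts
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise EmptyInputError("no genotypes")
    p = (2 * n_aa + n_ab) / (2 * n)
    expected = np.array([n * p * p, 2 * n * p * (1 - p),
                         n * (1 - p) * (1 - p)])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = 0.0
    for o, e in zip(observed, expected):
        if e > 0:
            chi2 += (o - e) ** 2 / e
        elif o > 0:
            chi2 = np.inf
    pval = float(stats.chi2.sf(chi2, df=1)) if np.isfinite(chi2) else 0.0
    return float(chi2), 1, pval


# --------------------------------------------------------- allelic 2x2


def risk_dosage_series(subjects: pd.DataFrame, rsid: str,
                       risk_allele: str) -> pd.Series:
    """Risk-allele dosage (0/1/2) per subject; NaN where ungenotyped."""
    def dose(g):
        pair = parse_genotype(g)
        if pair is None:
            return np.nan
        return float(sum(1 for a in pair if a == risk_allele))
    return subjects[rsid].map(dose)


def allele_table(subjects: pd.DataFrame, rsid: str,
                 risk_allele: str) -> Contingency2x2:
    """Allele-count 2x2: risk/other alleles in cases vs controls."""
    d = risk_dosage_series(subjects, rsid, risk_allele)
    case = subjects.status == "case"
    ok = d.notna()
    a = int(d[case & ok].sum())
    b = int(2 * (case & ok).sum() - a)
    c = int(d[~case & ok].sum())
    dd = int(2 * (~case & ok).sum() - c)
    return Contingency2x2(a, b, c, dd)


def allelic_association(t: Contingency2x2,
                        yates: bool = False) -> AssocResult:
    """Allelic odds ratio with Pearson chi-square p (no continuity
    correction unless ``yates``)."""
    if (t.a + t.b == 0 or t.c + t.d == 0 or t.a + t.c == 0
            or t.b + t.d == 0):
        raise DegenerateTableError("zero margin in allele table")
    or_, lo, hi, method = _cross_product_or(t)
    chi2, p, _, _ = stats.chi2_contingency(
        [[t.a, t.b], [t.c, t.d]], correction=yates)[:4]
    return AssocResult(model="allelic", odds_ratio=or_, ci_low=lo,
                       ci_high=hi, p_value=float(p),
                       n=t.a + t.b + t.c + t.d,
                       method=f"pearson-chi2/{method}")


# ------------------------------------------------- logistic model fits


def _code_genotype(dosage: pd.Series, model: str) -> pd.Series:
    if model == "additive":
        return dosage
    if model == "dominant":
        return (dosage >= 1).astype(float)
    if model == "recessive":
        return (dosage == 2).astype(float)
    raise InvalidInputError(f"unknown genetic model {model!r}")


def _design(subjects: pd.DataFrame,
            covariates: tuple[str, ...]) -> pd.DataFrame:
    """Numeric design columns: booleans to 0/1, categoricals to dummies."""
    if not covariates:
        return pd.DataFrame(index=subjects.index)
    cov = subjects.loc[:, list(covariates)].copy()
    for col in cov.columns:
        if cov[col].dtype == bool or str(cov[col].dtype) == "boolean":
            cov[col] = cov[col].astype(float)
    return pd.get_dummies(cov, drop_first=True, dtype=float)


def genetic_model_fit(subjects: pd.DataFrame, rsid: str, risk_allele: str,
                      model: str = "additive",
                      covariates: tuple[str, ...] = ()) -> AssocResult:
    """Logistic regression of case status on a coded genotype.

    The genotype enters as risk-allele dosage (additive), carrier
    indicator (dominant), or homozygous-risk indicator (recessive); OR is
    exp(coefficient) with a Wald 95% CI and p. A recessive fit requires at
    least one homozygous-risk subject in each status group (otherwise the
    model is unavailable, mirroring how monomorphic strata are reported).
    """
    dosage = risk_dosage_series(subjects, rsid, risk_allele)
    keep = dosage.notna()
    sub = subjects[keep]
    dosage = dosage[keep]
    y = (sub.status == "case").astype(float)
    if y.nunique() < 2:
        raise EmptyInputError("need at least one case and one control")
    if model == "recessive":
        hom = dosage == 2
        if not (hom & (y == 1)).any() or not (hom & (y == 0)).any():
            raise ModelUnavailableError(
                f"no homozygous-risk subjects in both groups for {rsid}")

    x = _code_genotype(dosage, model)
    X = pd.concat([x.rename("genotype"), _design(sub, covariates)], axis=1)
    X = sm.add_constant(X, has_constant="add")
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # separation / singular design
        raise NonEstimableError(f"logistic fit failed for {rsid}: {exc}")
    if not fit.mle_retvals.get("converged", True):
        raise NonEstimableError(
            f"logistic fit did not converge for {rsid} "
            "(possible perfect separation)")
    coef = fit.params["genotype"]
    se = fit.bse["genotype"]
    z = stats.norm.ppf(0.975)
    return AssocResult(
        model=model, odds_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(coef - z * se)),
        ci_high=float(np.exp(coef + z * se)),
        p_value=float(fit.pvalues["genotype"]),
        adjusted=bool(covariates), covariates=tuple(covariates),
        n=int(len(sub)), method="logistic-mle/wald")


def subgroup_and_interaction(subjects: pd.DataFrame, rsid: str,
                             risk_allele: str, model: str,
                             stratifier: str, cutpoint: float,
                             covariates: tuple[str, ...] = (),
                             ) -> tuple[dict[str, AssocResult], float]:
    """Stratified fits plus a Wald test of effect modification.

    Subjects split at ``cutpoint`` of a continuous ``stratifier`` (low:
    value < cutpoint). Each stratum gets its own fit; the interaction p
    comes from the genotype x stratum product term in the pooled model.
    """
    strata = {
        "low": subjects[subjects[stratifier] < cutpoint],
        "high": subjects[subjects[stratifier] >= cutpoint],
    }
    per_stratum: dict[str, AssocResult] = {}
    for name, sub in strata.items():
        if sub.empty or sub.status.nunique() < 2:
            continue  # stratum skipped; reported by absence
        try:
            per_stratum[name] = genetic_model_fit(
                sub, rsid, risk_allele, model, covariates)
        except (ModelUnavailableError, NonEstimableError):
            continue

    dosage = risk_dosage_series(subjects, rsid, risk_allele)
    keep = dosage.notna()
    sub = subjects[keep]
    x = _code_genotype(dosage[keep], model)
    high = (sub[stratifier] >= cutpoint).astype(float)
    X = pd.DataFrame({
        "genotype": x, "stratum": high, "genotype_x_stratum": x * high})
    X = pd.concat([X, _design(sub, covariates)], axis=1)
    X = sm.add_constant(X, has_constant="add")
    y = (sub.status == "case").astype(float)
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        interaction_p = float(fit.pvalues["genotype_x_stratum"])
    except Exception as exc:
        raise NonEstimableError(f"pooled interaction model failed: {exc}")
    return per_stratum, interaction_p


def genotype_combination(subjects: pd.DataFrame, rsid_a: str, rsid_b: str,
                         reference_pair: tuple[str, str],
                         min_count: int = 5) -> pd.DataFrame:
    """Cross-classified genotype-pair odds ratios against a reference cell.

    Genotypes are compared as unordered allele pairs. Each non-reference
    cell's OR is the 2x2 cross-product against the reference cell with a
    Woolf CI (+0.5 correction when a cell is empty); cells with fewer
    subjects than ``min_count`` are flagged.
    """
    def norm(g):
        pair = parse_genotype(g)
        return None if pair is None else "/".join(sorted(pair))

    ga = subjects[rsid_a].map(norm)
    gb = subjects[rsid_b].map(norm)
    keep = ga.notna() & gb.notna()
    sub = subjects[keep]
    combo = ga[keep] + " + " + gb[keep]
    ref_label = "/".join(sorted(reference_pair[0].split("/"))) + " + " + \
        "/".join(sorted(reference_pair[1].split("/")))
    case = sub.status == "case"

    ref_cases = int((case & (combo == ref_label)).sum())
    ref_ctrls = int((~case & (combo == ref_label)).sum())
    if ref_cases + ref_ctrls == 0:
        raise DegenerateTableError(f"empty reference cell {ref_label!r}")

    rows = []
    for label in sorted(combo.unique()):
        n_case = int((case & (combo == label)).sum())
        n_ctrl = int((~case & (combo == label)).sum())
        if label == ref_label:
            rows.append((label, n_case, n_ctrl, 1.0, np.nan, np.nan, None))
            continue
        t = Contingency2x2(n_case, n_ctrl, ref_cases, ref_ctrls)
        or_, lo, hi, _ = _cross_product_or(t)
        flag = "low-count" if (n_case + n_ctrl) < min_count else None
        rows.append((label, n_case, n_ctrl, or_, lo, hi, flag))
    return pd.DataFrame(rows, columns=["combination", "cases", "controls",
                                       "odds_ratio", "ci_low", "ci_high",
                                       "flag"])


def pack_years(units_per_day: float, years: float) -> float:
    """Pack-years of smoking: (units smoked per day / 20) x years smoked."""
    if units_per_day < 0 or years < 0:
        raise InvalidInputError("smoking inputs must be non-negative")
    return units_per_day / 20.0 * years


def genotype_counts(subjects: pd.DataFrame, rsid: str, ref: str,
                    alt: str, status: str | None = None,
                    ) -> tuple[int, int, int]:
    """(hom-ref, het, hom-alt) counts, optionally within one status."""
    sub = subjects if status is None else subjects[subjects.status == status]
    counts = [0, 0, 0]
    for g in sub[rsid]:
        pair = parse_genotype(g)
        if pair is None:
            continue
        counts[sum(1 for a in pair if a == alt)] += 1
    return tuple(counts)
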
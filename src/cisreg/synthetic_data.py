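"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the data layers a cis-regulatory prioritization study
queries from public resources: a three-group expression matrix (healthy
non-smokers HNS, healthy smokers HS, smokers with lung cancer SLC), DNase I
hypersensitive sites (DHS) with per-sample signal, an annotated variant
table, and a case-control cohort with survival follow-up. Effects are
*planted* at known loci so downstream estimators can be checked for
recovery, and deterministic failure stages are assigned to null variants so
cascade bookkeeping has an exact expected answer.

A single master seed drives all generators through independent derived
streams (``default_rng([seed, stream_id])``), so each table is reproducible
on its own and tables are mutually uncorrelated.

``table3_fixture`` expands printed genotype-by-status counts for the three
genotyped promoter variants (rs3764821, rs3748523, rs5742926) into
subject-level records whose cross-tabulations match the counts exactly.
"""

from __future__ import annotations

import json
import math
from typing import NamedTuple

import numpy as np
import pandas as pd

from .config import SimConfig
from .errors import InvalidConfigError

GROUPS = ("HNS", "HS", "SLC")

# stable stream ids; never renumber, or seeds stop reproducing old tables
_STREAMS = {
    "expression": 1,
    "dhs": 2,
    "snv": 3,
    "cohort": 4,
    "population": 5,
}

REGIMENS = (
    "Docetaxel cis/carboplatin",
    "Pemetrexed cis/carboplatin",
    "Paclitaxel cis/carboplatin",
    "Nanopaclitaxel cis/carboplatin",
    "Etoposide cis/carboplatin",
)
SECOND_LINE = (
    "Gemcitabine cis/carboplatin",
    "Nanopaclitaxel cis/carboplatin",
    "Paclitaxel cis/carboplatin",
)
THIRD_LINE = ("Eribulin cis/carboplatin",)

RESPONSES = ("complete", "partial", "stable", "poor", "progressive")
EXPOSURES = ("alcohol", "tobacco_chewing", "betel_quid", "wood_smoke",
             "coal_smoke", "asbestos", "pesticide")

# markers carried by the simulated cohort; the first carries the planted
# case-control and survival effects (risk allele = alt)
COHORT_MARKERS = (
    ("snvE1", "A", "G", 0.15),
    ("snvN1", "C", "G", 0.25),
    ("snvN2", "G", "T", 0.07),
)

# genotype-by-status counts for the three genotyped promoter variants
# (counts as printed; control sums below the cohort size are modelled as
# per-marker missing genotypes)
TABLE3_COUNTS = {
    "rs3764821": {"alleles": ("A", "G"), "case": (71, 28, 2),
                  "control": (345, 53, 1)},
    "rs3748523": {"alleles": ("C", "G"), "case": (54, 41, 6),
                  "control": (269, 122, 10)},
    "rs5742926": {"alleles": ("G", "T"), "case": (94, 7, 0),
                  "control": (346, 51, 0)},
}
TABLE3_N_CASES = 101
TABLE3_N_CONTROLS = 401


def _rng(cfg: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, _STREAMS[stream]])


def gene_annotation(cfg: SimConfig) -> pd.DataFrame:
    """Gene table: name, pathway, chromosome, TSS, planted flag.

    Genes alternate between chromosomes and are spaced 1 Mb apart so the
    +/-100 kb DHS windows of distinct genes never overlap.
    """
    n = cfg.n_genes
    n_xmg = (n + 1) // 2
    rows = []
    for i in range(n):
        pathway = "XMG" if i < n_xmg else "DRG"
        name = f"{pathway}{i + 1:03d}"
        chrom = f"chr{1 + i % 22}"
        tss = 1_000_000 + 1_000_000 * (i // 22)
        rows.append((name, pathway, chrom, tss, i < cfg.n_planted_genes))
    return pd.DataFrame(
        rows, columns=["gene", "pathway", "chrom", "tss", "planted"]
    )


class ExpressionTables(NamedTuple):
    table: pd.DataFrame   # long: gene, pathway, group, replicate, expression
    truth: pd.DataFrame   # gene, pathway, planted


def gen_expression_table(cfg: SimConfig) -> ExpressionTables:
    """Three-group expression table with planted reciprocal patterns.

    Planted genes follow category (a): mean expression up in HS vs HNS and
    down in SLC vs HS, both by ``planted_fold_change``. Remaining genes
    share one mean across groups. Noise is log-normal (normal on log2
    scale), the standard multiplicative model for expression intensities.
    """
    cfg.validate()
    if cfg.n_samples_per_group <= 0:
        raise InvalidConfigError("n_samples_per_group must be positive")
    rng = _rng(cfg, "expression")
    genes = gene_annotation(cfg)
    n_rep = cfg.n_samples_per_group
    log_fc = math.log2(cfg.planted_fold_change)

    rows = []
    for _, g in genes.iterrows():
        base = rng.normal(6.0, 1.0)
        means = {"HNS": base, "HS": base, "SLC": base}
        if g.planted:
            means["HS"] = base + log_fc
            means["SLC"] = base  # down vs HS by the same fold change
        for group in GROUPS:
            vals = 2.0 ** rng.normal(means[group], cfg.expression_noise_sd,
                                     n_rep)
            for rep, v in enumerate(vals):
                rows.append((g.gene, g.pathway, group, rep, v))
    table = pd.DataFrame(
        rows, columns=["gene", "pathway", "group", "replicate", "expression"]
    )
    return ExpressionTables(table, genes[["gene", "pathway", "planted"]])


def expression_records(table: pd.DataFrame) -> pd.DataFrame:
    """Summarize a long expression table into per-gene comparison records.

    Set A compares HS against HNS; Set B compares SLC against HS. Fold
    change is the ratio of group geometric means oriented so it is >= 1,
    with the direction carried separately; p is a Welch t-test on log2
    values.
    """
    from scipy import stats

    out = []
    for (gene, pathway), sub in table.groupby(["gene", "pathway"], sort=True):
        by = {g: np.log2(sub.loc[sub.group == g, "expression"].to_numpy())
              for g in GROUPS}
        for comparison, (ref, alt_) in (("SetA", ("HNS", "HS")),
                                        ("SetB", ("HS", "SLC"))):
            a, b = by[ref], by[alt_]
            if len(a) < 2 or len(b) < 2:
                continue
            diff = b.mean() - a.mean()
            fc = 2.0 ** abs(diff)
            direction = "up" if diff >= 0 else "down"
            p = stats.ttest_ind(b, a, equal_var=False).pvalue
            out.append((gene, pathway, comparison, fc, direction, float(p)))
    return pd.DataFrame(
        out, columns=["gene", "pathway", "comparison", "fold_change",
                      "direction", "p_value"],
    )


class DhsSnvTables(NamedTuple):
    dhs: pd.DataFrame        # chrom,start,end,gene,planted_corr + signal cols
    snvs: pd.DataFrame       # annotation table, nested fields JSON-encoded
    gene_expr: pd.DataFrame  # per-gene expression vectors (genes x samples)


_SCORE_CLASSES_KEEP = ("1a", "1b", "1c", "1d", "1e", "1f", "2a", "2b", "2c",
                       "3a", "3b", "4")
_SCORE_CLASSES_DROP = ("5", "6")

# deterministic failure stage cycled over null variants so cascade counts
# have an exact expected value; every null fails at or before the eQTL
# stage, so the eQTL-stage survivors are exactly the planted variants
_FAIL_STAGES = ("dhs", "regulatory", "regulome", "eqtl")


def gen_dhs_and_snvs(cfg: SimConfig, planted_r: float = 0.9) -> DhsSnvTables:
    """DHS intervals with per-sample DNase signal, plus an annotated SNV set.

    Each gene receives ``n_dhs_per_gene`` intervals inside +/-100 kb of its
    TSS; the first ``n_corr_dhs_per_gene`` carry signal correlated with the
    gene's expression vector at level ``planted_r`` (on the log scale).
    Planted variants sit strictly inside a correlated DHS of a planted gene
    and carry pass-all annotations; each null variant is assigned one
    failure stage so the cascade's survivor counts are exact by
    construction.
    """
    cfg.validate()
    rng = _rng(cfg, "dhs")
    snv_rng = _rng(cfg, "snv")
    genes = gene_annotation(cfg)
    n_samp = cfg.n_samples_per_group

    # per-gene expression vectors (log scale latent, exported linear)
    expr_log = {g: rng.normal(5.0, 1.0, n_samp) for g in genes.gene}
    gene_expr = pd.DataFrame(
        {g: 2.0 ** v for g, v in expr_log.items()}
    ).T
    gene_expr.columns = [f"sample_{i}" for i in range(n_samp)]
    gene_expr.index.name = "gene"

    window = 100_000
    dhs_rows = []
    for _, g in genes.iterrows():
        z = expr_log[g.gene]
        z = (z - z.mean()) / z.std()
        for j in range(cfg.n_dhs_per_gene):
            width = int(rng.integers(150, 400))
            mid = g.tss + int(rng.integers(-(window - 1000), window - 1000))
            start = max(0, mid - width // 2)
            end = start + width
            correlated = j < cfg.n_corr_dhs_per_gene
            if correlated:
                noise = rng.normal(0, 1, n_samp)
                sig_log = planted_r * z + math.sqrt(1 - planted_r ** 2) * noise
            else:
                sig_log = rng.normal(0, 1, n_samp)
            signal = 2.0 ** (sig_log + 5.0)
            dhs_rows.append(
                (g.chrom, start, end, g.gene, correlated, *signal)
            )
    sig_cols = [f"sample_{i}" for i in range(n_samp)]
    dhs = pd.DataFrame(
        dhs_rows,
        columns=["chrom", "start", "end", "gene", "planted_corr", *sig_cols],
    )

    # --- variants -----------------------------------------------------
    planted_genes = genes[genes.planted]
    if cfg.n_planted_snvs and planted_genes.empty:
        raise InvalidConfigError(
            "planted SNVs require at least one planted gene")
    bases = np.array(list("ACGT"))
    pops = [f"POP{i + 1}" for i in range(cfg.n_populations)]

    def alleles() -> tuple[str, str]:
        ref, alt_ = snv_rng.choice(4, size=2, replace=False)
        return bases[ref], bases[alt_]

    rows = []
    for i in range(cfg.n_snvs):
        planted = i < cfg.n_planted_snvs
        shortlisted = i < cfg.n_shortlist_snvs
        rsid = f"rs{900000 + i}"
        ref, alt = alleles()
        fail = None if planted else _FAIL_STAGES[i % len(_FAIL_STAGES)]

        if planted:
            g = planted_genes.iloc[i % len(planted_genes)]
        else:
            g = genes.iloc[i % len(genes)]

        gene_dhs = dhs[dhs.gene == g.gene].reset_index(drop=True)
        if fail == "dhs":
            # outside every interval and outside the gene's 100 kb window
            pos = int(g.tss) + 120_000 + i  # 1-based
        else:
            target = gene_dhs.iloc[0 if planted else i % len(gene_dhs)]
            offset = int(snv_rng.integers(1, target.end - target.start - 1))
            pos = int(target.start) + 1 + offset  # strictly inside, 1-based

        is_regulatory = fail != "regulatory"
        if fail == "regulome":
            score_class = _SCORE_CLASSES_DROP[i % 2]
        else:
            score_class = _SCORE_CLASSES_KEEP[i % len(_SCORE_CLASSES_KEEP)]

        if planted:
            eqtl_p = 1e-6 if shortlisted else 0.02
            eqtl = [{"tissue": "Lung", "effect_allele": alt,
                     "beta": cfg.eqtl_beta, "p": eqtl_p}]
        elif fail == "eqtl":
            if i % 2:
                eqtl = [{"tissue": "Lung", "effect_allele": alt,
                         "beta": 0.1, "p": 0.5}]
            else:  # conflicting lung entries -> ambiguous, dropped
                eqtl = [
                    {"tissue": "Lung", "effect_allele": alt,
                     "beta": 0.3, "p": 0.01},
                    {"tissue": "Lung", "effect_allele": alt,
                     "beta": -0.3, "p": 0.01},
                ]
        else:
            eqtl = [{"tissue": "Lung", "effect_allele": alt,
                     "beta": float(snv_rng.normal(0, 0.1)), "p": 0.03}]

        lung_dhs_present = fail != "lung_dhs"
        if planted:
            chromatin = ("Active TSS" if shortlisted else
                         ("Active Enhancer 1", "Quiescent")[i % 2])
            tfbs = [{"tf": f"TF{i + 1}", "pwm_id": f"PWM{i + 1}",
                     "score_ref": 2.0, "score_alt": 7.5,
                     "direction": "gain", "p_impact": 1e-4,
                     "tf_expressed_in_lung": True}]
            cancer = [{"cohort": "LUAD", "beta": cfg.eqtl_beta * 0.6,
                       "t": -4.0, "p": 1e-4, "fdr_q": 1e-3}]
        else:
            chromatin = ("Quiescent", "Weak Enhancer 1",
                         "Heterochromatin")[i % 3]
            tfbs = []
            cancer = []

        freqs = {p: float(snv_rng.uniform(0.05, 0.5)) for p in pops}
        rows.append({
            "rsid": rsid, "chrom": g.chrom, "pos": pos, "ref": ref,
            "alt": alt, "gene": g.gene, "is_regulatory": is_regulatory,
            "score_class": score_class, "eqtl": json.dumps(eqtl),
            "cancer_eqtl": json.dumps(cancer),
            "chromatin_state": chromatin,
            "lung_dhs_present": lung_dhs_present,
            "tfbs": json.dumps(tfbs),
            "pop_freq": json.dumps(freqs),
            "planted": planted, "shortlisted": shortlisted,
            "fail_stage": fail or "",
        })
    snvs = pd.DataFrame(rows)
    return DhsSnvTables(dhs, snvs, gene_expr)


def _draw_genotypes(rng: np.random.Generator, ref: str, alt: str,
                    freq_alt: float, n: int) -> np.ndarray:
    """n genotype strings drawn under Hardy-Weinberg equilibrium."""
    dosage = rng.binomial(2, freq_alt, n)
    gmap = np.array([f"{ref}/{ref}", f"{ref}/{alt}", f"{alt}/{alt}"])
    return gmap[dosage]


def gen_cohort(cfg: SimConfig) -> pd.DataFrame:
    """Case-control cohort with survival follow-up for the cases.

    Genotypes are drawn under Hardy-Weinberg equilibrium in the source
    population; case status follows a logistic model with per-risk-allele
    log odds ``effect_log_or`` at the first marker. Survival times are
    exponential with hazard multiplied by ``hazard_ratio_true`` for risk
    carriers (dominant collapse), censored independently so the expected
    censored fraction equals ``censor_rate``. Covariates: age truncated
    normal on [30, 90], sex heavily male (matching a smoking cohort),
    pack-years from simulated consumption via (units/day / 20) x years,
    binary environmental exposures, categorical regimen sequences and
    treatment responses.
    """
    cfg.validate()
    if cfg.n_cases + cfg.n_controls == 0:
        raise InvalidConfigError("n_cases + n_controls must be positive")
    rng = _rng(cfg, "cohort")

    n_target = cfg.n_cases + cfg.n_controls
    pool = max(20 * n_target, 2000)
    dosage = {m: rng.binomial(2, f, pool) for m, _, _, f in COHORT_MARKERS}
    # baseline prevalence ~15% so both strata fill quickly
    eta = math.log(0.15 / 0.85) + cfg.effect_log_or * dosage[
        COHORT_MARKERS[0][0]]
    is_case = rng.random(pool) < 1.0 / (1.0 + np.exp(-eta))

    case_idx = np.flatnonzero(is_case)[: cfg.n_cases]
    ctrl_idx = np.flatnonzero(~is_case)[: cfg.n_controls]
    if len(case_idx) < cfg.n_cases or len(ctrl_idx) < cfg.n_controls:
        raise InvalidConfigError(
            "simulation pool exhausted; lower n_cases/n_controls")
    idx = np.concatenate([case_idx, ctrl_idx])
    n = len(idx)
    n_cases = len(case_idx)
    status = np.array(["case"] * n_cases + ["control"] * len(ctrl_idx))

    df = pd.DataFrame({"id": [f"S{i + 1:05d}" for i in range(n)],
                       "status": status})
    for m, ref, alt, _ in COHORT_MARKERS:
        gmap = np.array([f"{ref}/{ref}", f"{ref}/{alt}", f"{alt}/{alt}"])
        df[m] = gmap[dosage[m][idx]]

    age = rng.normal(63, 10, n).clip(30, 90)
    df["age"] = np.round(age, 1)
    df["sex"] = np.where(rng.random(n) < 0.93, "male", "female")
    units = rng.poisson(12, n) + 1
    years = rng.normal(35, 10, n).clip(1, 70)
    df["pack_years"] = np.round(pack_years_formula(units, years), 2)
    for name, prob in zip(EXPOSURES, (0.4, 0.3, 0.2, 0.25, 0.2, 0.05, 0.1)):
        df[name] = rng.random(n) < prob

    df["histology"] = None
    df["stage"] = None
    df["metastasis"] = None
    hist = rng.choice(["ADC", "SqCC", "SCLC", "other"], n_cases,
                      p=[0.5, 0.38, 0.11, 0.01])
    stage = rng.choice(["I", "II", "III", "IV"], n_cases,
                       p=[0.02, 0.11, 0.48, 0.39])
    df.loc[: n_cases - 1, "histology"] = hist
    df.loc[: n_cases - 1, "stage"] = stage
    df.loc[: n_cases - 1, "metastasis"] = rng.random(n_cases) < 0.9

    # survival for cases: exponential, dominant carrier effect at marker 1
    carrier = dosage[COHORT_MARKERS[0][0]][case_idx] > 0
    lam = (1.0 / 12.0) * np.where(carrier, cfg.hazard_ratio_true, 1.0)
    t_event = rng.exponential(1.0 / lam)
    df["time_months"] = np.nan
    df["event"] = pd.array([pd.NA] * n, dtype="boolean")
    if cfg.censor_rate > 0:
        lam_c = lam * cfg.censor_rate / (1.0 - cfg.censor_rate)
        t_cens = rng.exponential(1.0 / lam_c)
    else:
        t_cens = np.full(n_cases, np.inf)
    time = np.minimum(t_event, t_cens)
    df.loc[: n_cases - 1, "time_months"] = np.round(
        np.maximum(time, 0.1), 2)
    df.loc[: n_cases - 1, "event"] = t_event <= t_cens

    df["response"] = None
    df.loc[: n_cases - 1, "response"] = rng.choice(
        RESPONSES, n_cases, p=[0.1, 0.3, 0.25, 0.15, 0.2])
    for col in ("regimen_1", "regimen_2", "regimen_3"):
        df[col] = None
    df.loc[: n_cases - 1, "regimen_1"] = rng.choice(REGIMENS, n_cases)
    nonresp = (df.response.isin(["stable", "poor", "progressive"])
               & (df.status == "case"))
    second = rng.choice(SECOND_LINE, int(nonresp.sum()))
    df.loc[nonresp, "regimen_2"] = second
    third = nonresp & (rng.random(n) < 0.2)
    df.loc[third, "regimen_3"] = rng.choice(THIRD_LINE, int(third.sum()))
    return df


def pack_years_formula(units_per_day, years):
    """Smoking exposure: (units smoked per day / 20) x years smoked."""
    return np.asarray(units_per_day, dtype=float) / 20.0 * np.asarray(
        years, dtype=float)


def table3_fixture() -> pd.DataFrame:
    """Subject-level expansion of the printed genotype-by-status counts.

    Returns 101 cases and 401 controls. For each marker the genotype
    cross-tabulation by status matches the printed counts exactly; control
    genotype sums below 401 (399 for rs3764821, 397 for rs5742926) are
    represented as per-marker missing genotypes, mirroring per-marker
    genotyping failures.
    """
    def expand(marker_counts, alleles, group_n):
        ref, alt = alleles
        cells = [f"{ref}/{ref}", f"{ref}/{alt}", f"{alt}/{alt}"]
        out = []
        for geno, k in zip(cells, marker_counts):
            out.extend([geno] * k)
        out.extend([None] * (group_n - len(out)))
        return out

    data = {"id": [f"case{i + 1:04d}" for i in range(TABLE3_N_CASES)]
                  + [f"ctrl{i + 1:04d}" for i in range(TABLE3_N_CONTROLS)],
            "status": ["case"] * TABLE3_N_CASES
                      + ["control"] * TABLE3_N_CONTROLS}
    for rsid, entry in TABLE3_COUNTS.items():
        data[rsid] = (expand(entry["case"], entry["alleles"], TABLE3_N_CASES)
                      + expand(entry["control"], entry["alleles"],
                               TABLE3_N_CONTROLS))
    return pd.DataFrame(data)


def gen_population_genotypes(freqs: dict[str, float], alleles:
                             dict[str, tuple[str, str]], n_subjects: int,
                             seed: int) -> pd.DataFrame:
    """Genotype matrix for one population drawn under HWE.

    ``freqs`` maps rsid to the alt-allele frequency; ``alleles`` maps rsid
    to (ref, alt). Used to build per-population panels for genetic risk
    score ranking.
    """
    rng = np.random.default_rng(seed)
    data = {}
    for rsid, f in freqs.items():
        ref, alt = alleles[rsid]
        data[rsid] = _draw_genotypes(rng, ref, alt, f, n_subjects)
    df = pd.DataFrame(data)
    df.insert(0, "id", [f"P{i + 1:05d}" for i in range(n_subjects)])
    return df
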
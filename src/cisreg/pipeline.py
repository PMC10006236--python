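"""End-to-end orchestration of the prioritization and association stages.

``run_pipeline`` drives: expression-based gene selection, DHS-expression
correlation with permutation nulls, variant-to-DHS mapping, the regulatory
cascade, a regulatory-annotation enrichment test against a sampled variant
universe, risk-score ranking of simulated populations, case-control
association at the cohort's planted marker, and survival analysis — writing
per-stage TSVs and one machine-readable JSON summary. Every stage logs its
input and output counts; the cascade counts are asserted non-increasing on
every run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import (association_stats, dhs_mapping, enrichment_ld, formats,
               gene_selection, regulatory_cascade, risk_scores,
               survival_stats, synthetic_data)
from .config import PipelineConfig
from .errors import (EmptyInputError, ModelUnavailableError,
                     NonEstimableError)

log = logging.getLogger("cisreg")

_INPUT_TABLES = ("expression.tsv", "dhs.tsv", "snvs.tsv", "gene_expr.tsv",
                 "cohort.tsv", "genes.tsv")


def simulate_inputs(cfg: PipelineConfig, out_dir: Path) -> None:
    """Materialize every synthetic input table under ``out_dir``."""
    out_dir.mkdir(parents=True, exist_ok=True)
    expr = synthetic_data.gen_expression_table(cfg.sim)
    formats.write_tsv(expr.table, out_dir / "expression.tsv")
    tables = synthetic_data.gen_dhs_and_snvs(cfg.sim)
    formats.write_tsv(tables.dhs, out_dir / "dhs.tsv")
    formats.write_tsv(tables.snvs, out_dir / "snvs.tsv")
    formats.write_tsv(tables.gene_expr.reset_index(),
                      out_dir / "gene_expr.tsv")
    formats.write_tsv(synthetic_data.gene_annotation(cfg.sim),
                      out_dir / "genes.tsv")
    formats.write_tsv(synthetic_data.gen_cohort(cfg.sim),
                      out_dir / "cohort.tsv")
    formats.write_tsv(synthetic_data.table3_fixture(),
                      out_dir / "table3.tsv")


def _load_inputs(cfg: PipelineConfig):
    if cfg.input_dir is not None:
        d = Path(cfg.input_dir)
        expr_table = formats.read_tsv(d / "expression.tsv")
        dhs = formats.read_tsv(d / "dhs.tsv")
        snvs = formats.read_tsv(d / "snvs.tsv")
        gene_expr = formats.read_tsv(d / "gene_expr.tsv").set_index("gene")
        genes = formats.read_tsv(d / "genes.tsv")
        cohort = formats.read_tsv(d / "cohort.tsv")
    else:
        expr_table = synthetic_data.gen_expression_table(cfg.sim).table
        tables = synthetic_data.gen_dhs_and_snvs(cfg.sim)
        dhs, snvs, gene_expr = tables.dhs, tables.snvs, tables.gene_expr
        genes = synthetic_data.gene_annotation(cfg.sim)
        cohort = synthetic_data.gen_cohort(cfg.sim)
    return expr_table, dhs, snvs, gene_expr, genes, cohort


def validate_inputs(cfg: PipelineConfig) -> list[str]:
    """Schema diagnostics for an input directory; empty list means clean.
    Never mutates inputs; unreadable files are collected as diagnostics."""
    diags: list[str] = []
    if cfg.input_dir is None:
        return diags
    d = Path(cfg.input_dir)
    for name in _INPUT_TABLES:
        if not (d / name).exists():
            diags.append(f"{name}: missing")
    if diags:
        return diags
    try:
        dhs = formats.read_tsv(d / "dhs.tsv")
        bad = dhs[dhs.start >= dhs.end]
        for i in bad.index:
            diags.append(f"dhs.tsv row {i}: start >= end")
    except Exception as exc:
        diags.append(f"dhs.tsv: unreadable ({exc})")
    try:
        snvs = formats.read_tsv(d / "snvs.tsv")
        dup = snvs[snvs.rsid.duplicated()]
        for r in dup.rsid:
            diags.append(f"snvs.tsv: duplicate rsid {r}")
    except Exception as exc:
        diags.append(f"snvs.tsv: unreadable ({exc})")
    try:
        expr = formats.read_tsv(d / "expression.tsv")
        need = {"gene", "pathway", "group", "replicate", "expression"}
        missing = need - set(expr.columns)
        if missing:
            diags.append(f"expression.tsv: missing columns "
                         f"{sorted(missing)}")
    except Exception as exc:
        diags.append(f"expression.tsv: unreadable ({exc})")
    return diags


def _dhs_regions(dhs: pd.DataFrame, gene_expr: pd.DataFrame,
                 thresholds, seed: int) -> list[dhs_mapping.DhsRegion]:
    """Score every interval's DNase-expression correlation against a null
    pool of signal vectors from other chromosomes."""
    sig_cols = [c for c in dhs.columns if c.startswith("sample_")]
    regions = []
    signals = dhs[sig_cols].to_numpy()
    for i, row in dhs.iterrows():
        expr = gene_expr.loc[row.gene].to_numpy(dtype=float)
        pool_idx = np.flatnonzero((dhs.chrom != row.chrom).to_numpy())
        pool = [signals[j] for j in pool_idx]
        reg = dhs_mapping.DhsRegion(
            chrom=row.chrom, start=int(row.start), end=int(row.end),
            gene=row.gene, signal=signals[i])
        try:
            r, p = dhs_mapping.dhs_expression_correlation(
                signals[i], expr, pool, n_perm=thresholds.n_perm,
                seed=seed + i)
        except Exception:
            continue
        reg.r, reg.p_perm = r, p
        regions.append(reg)
    return regions


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages and write outputs; returns the summary dict."""
    cfg.validate()
    diags = validate_inputs(cfg)
    if diags:
        raise EmptyInputError("input validation failed: " + "; ".join(diags))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = cfg.thresholds
    seed = cfg.sim.seed
    summary: dict = {"seed": seed, "thresholds": asdict(th), "stages": {}}

    expr_table, dhs, snvs, gene_expr, genes, cohort = _load_inputs(cfg)

    # 1. gene selection --------------------------------------------------
    records = synthetic_data.expression_records(expr_table)
    calls = gene_selection.select_genes(records, th.fold_change,
                                        th.expression_alpha)
    directions = gene_selection.slc_directions(calls)
    formats.write_tsv(calls, out / "gene_calls.tsv")
    summary["stages"]["gene_selection"] = {
        "n_genes_in": int(calls.shape[0]),
        "n_selected": int(calls.selected.sum())}
    log.info("gene_selection: %d -> %d", len(calls), calls.selected.sum())

    # 2. DHS correlation, top-k, SNV mapping -----------------------------
    regions = _dhs_regions(dhs, gene_expr, th, seed)
    tss = dict(zip(genes.gene, genes.tss))
    selected_regions = []
    for gene in calls.loc[calls.selected, "gene"]:
        selected_regions.extend(dhs_mapping.select_candidate_dhs(
            gene, regions, tss, k=th.dhs_k, alpha=th.dhs_alpha,
            window_kb=th.window_kb))
    snv_records = [
        dhs_mapping.SnvRecord(rsid=r.rsid, chrom=r.chrom, pos=int(r.pos),
                              ref=r.ref, alt=r.alt)
        for r in snvs.itertuples()]
    assigned, sign_counts = dhs_mapping.map_snvs_to_dhs(snv_records,
                                                        selected_regions)
    in_dhs = {s.rsid for s in assigned if s.assigned_dhs is not None}
    formats.write_bed(selected_regions, out / "candidate_dhs.bed")
    summary["stages"]["dhs_mapping"] = {
        "n_dhs_scored": len(regions),
        "n_dhs_selected": len(selected_regions),
        "n_snvs_in_dhs": len(in_dhs),
        "assignment_sign_counts": sign_counts}
    log.info("dhs_mapping: %d candidate DHS, %d SNVs inside",
             len(selected_regions), len(in_dhs))

    # 3. regulatory cascade ----------------------------------------------
    anns = regulatory_cascade.annotations_from_frame(snvs,
                                                     in_dhs_rsids=in_dhs)
    cascade = regulatory_cascade.run_cascade(anns, directions, th)
    summary["stages"]["cascade"] = {
        "counts": {k: cascade.state.counts[k]
                   for k in cascade.state.stage_names},
        "n_polymorphic": len(cascade.polymorphic),
        "shortlist": sorted(cascade.shortlist)}
    survivors_df = pd.DataFrame(
        [(a.rsid, a.gene, a.score_class, a.chromatin_state, a.risk_allele,
          regulatory_cascade.global_maf(a))
         for a in cascade.survivors],
        columns=["rsid", "gene", "score_class", "chromatin_state",
                 "risk_allele", "global_maf"])
    formats.write_tsv(survivors_df, out / "cascade_survivors.tsv")
    log.info("cascade: %s", summary["stages"]["cascade"]["counts"])

    # 4. enrichment of the regulatory flag vs a sampled universe ---------
    universe = enrichment_ld.sample_universe(
        list(snvs.rsid), n=min(100, len(snvs)), seed=seed)
    reg_flag = dict(zip(snvs.rsid, snvs.is_regulatory))
    dhs_set = cascade.state.survivors_per_stage["dhs"]
    a = sum(reg_flag[r] for r in dhs_set)
    c = sum(reg_flag[r] for r in universe)
    enr = enrichment_ld.fisher_2x2(enrichment_ld.Contingency2x2(
        a, len(dhs_set) - a, c, len(universe) - c))
    summary["stages"]["enrichment"] = {
        "odds_ratio": round(enr.odds_ratio, 4),
        "ci": [round(enr.ci_low, 4), round(enr.ci_high, 4)],
        "p_value": float(f"{enr.p_value:.6g}")}

    # 5. risk scores across simulated populations ------------------------
    if cascade.survivors:
        panel = risk_scores.RiskPanel(
            loci=[(a_.rsid, a_.risk_allele) for a_ in cascade.survivors],
            alleles={a_.rsid: (a_.ref, a_.alt) for a_ in cascade.survivors})
        pops = sorted({p for a_ in cascade.survivors for p in a_.pop_freq})
        panels = {}
        for k, pop in enumerate(pops):
            freqs = {}
            alleles = {}
            for a_ in cascade.survivors:
                f_risk = a_.pop_freq[pop]
                f_alt = f_risk if a_.risk_allele == a_.alt else 1 - f_risk
                freqs[a_.rsid] = f_alt
                alleles[a_.rsid] = (a_.ref, a_.alt)
            panels[pop] = synthetic_data.gen_population_genotypes(
                freqs, alleles, n_subjects=100, seed=seed * 1000 + k)
        ranking = risk_scores.population_ugrs_ranking(panel, panels)
        formats.write_tsv(ranking, out / "population_ugrs.tsv")
        summary["stages"]["ugrs"] = {
            "ranking": [[r.population, round(r.mean_ugrs, 3)]
                        for r in ranking.itertuples()]}

    # 6. case-control association ----------------------------------------
    marker, ref, alt, _ = synthetic_data.COHORT_MARKERS[0]
    controls = cohort[cohort.status == "control"]
    hwe = association_stats.hwe_test(
        association_stats.genotype_counts(controls, marker, ref, alt))
    assoc_rows = []
    allelic = association_stats.allelic_association(
        association_stats.allele_table(cohort, marker, alt))
    assoc_rows.append(("allelic", False, allelic))
    for model in association_stats.MODELS:
        for covs in ((), association_stats.DEFAULT_COVARIATES):
            try:
                res = association_stats.genetic_model_fit(
                    cohort, marker, alt, model, covs)
            except (ModelUnavailableError, NonEstimableError):
                continue
            assoc_rows.append((model, bool(covs), res))
    assoc_df = pd.DataFrame(
        [(m, adj, r.odds_ratio, r.ci_low, r.ci_high, r.p_value, r.n)
         for m, adj, r in assoc_rows],
        columns=["model", "adjusted", "odds_ratio", "ci_low", "ci_high",
                 "p_value", "n"])
    formats.write_tsv(assoc_df, out / "association.tsv")
    summary["stages"]["association"] = {
        "marker": marker,
        "hwe_controls": {"chi2": round(hwe[0], 4), "p": round(hwe[2], 4)},
        "models": [[m, adj, round(r.odds_ratio, 4)]
                   for m, adj, r in assoc_rows]}

    # 7. survival ---------------------------------------------------------
    cases = cohort[cohort.status == "case"].copy()
    cases["carrier"] = survival_stats.carrier_indicator(cases, marker, alt)
    cases = cases[cases.carrier.notna() & cases.time_months.notna()]
    cases["event"] = cases.event.astype(bool)
    grp0 = cases[cases.carrier == 0]
    grp1 = cases[cases.carrier == 1]
    surv: dict = {"marker": marker, "n": int(len(cases))}
    if len(grp0) and len(grp1) and cases.event.any():
        stat, p = survival_stats.logrank_test(
            grp0.time_months, grp0.event, grp1.time_months, grp1.event)
        surv["logrank"] = {"chi2": round(stat, 4), "p": round(p, 5)}
        for name, covs in (("crude", ()),
                           ("adjusted", survival_stats.SURVIVAL_COVARIATES)):
            try:
                res = survival_stats.cox_fit(cases, "carrier", covs)
                surv[f"cox_{name}"] = {
                    "hr": round(res.hazard_ratio, 4),
                    "ci": [round(res.ci_low, 4), round(res.ci_high, 4)],
                    "p": round(res.p_value, 5)}
            except (NonEstimableError, EmptyInputError) as exc:
                surv[f"cox_{name}"] = {"non_estimable": str(exc)}
        _, median0 = survival_stats.km_estimate(grp0.time_months, grp0.event)
        _, median1 = survival_stats.km_estimate(grp1.time_months, grp1.event)
        surv["median_os_months"] = {
            "reference": median0 if median0 is not None else "NR",
            "carrier": median1 if median1 is not None else "NR"}
    summary["stages"]["survival"] = surv

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
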
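"""The variant prioritization cascade.

Variants mapped into expression-correlated DHSs pass through ordered
filters: a regulatory-evidence flag, a regulatory score class (kept when at
least as strong as class 4), a lung cis-eQTL requirement with risk-allele
inference oriented by the gene's expression direction in the cancer group,
and presence in a lung-tissue DHS. Allele-specific transcription-factor
binding impacts (gain/loss of a PWM match with an exact enumerated
p-value) are recorded for survivors; by default they annotate rather than
filter, since binding predictions describe mechanism rather than gate the
statistical evidence. Survivor sets are strictly nested and counted per
stage.

PWM impact p-values use exact dynamic programming over the discretized
log-odds score distribution under the background model, so for short
motifs they equal brute-force enumeration over all sequences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .config import Thresholds
from .errors import (InvalidAnnotationError, InvalidInputError,
                     InvalidMotifError, MissingAnnotationError)

# ---------------------------------------------------------------- types

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class EqtlEntry:
    tissue: str
    effect_allele: str
    beta: float
    p: float


@dataclass
class CancerEqtl:
    cohort: str  # LUAD or LUSC
    beta: float
    t: float
    p: float
    fdr_q: float


@dataclass
class TfbsImpact:
    tf: str
    pwm_id: str
    score_ref: float
    score_alt: float
    direction: str  # gain, loss, none
    p_impact: float
    tf_expressed_in_lung: bool = True


@dataclass
class SnvAnnotation:
    rsid: str
    gene: str
    ref: str
    alt: str
    is_regulatory: bool = False
    score_class: str = "6"
    eqtl: list[EqtlEntry] = field(default_factory=list)
    cancer_eqtl: list[CancerEqtl] = field(default_factory=list)
    chromatin_state: str = "Quiescent"
    lung_dhs_present: bool = False
    tfbs_impacts: list[TfbsImpact] = field(default_factory=list)
    pop_freq: dict[str, float] = field(default_factory=dict)
    risk_allele: str | None = None
    in_dhs: bool = False


@dataclass
class CascadeState:
    stage_names: list[str]
    survivors_per_stage: dict[str, set[str]]
    counts: dict[str, int]

    def check_nested(self) -> None:
        prev = None
        for name in self.stage_names:
            cur = self.survivors_per_stage[name]
            if self.counts[name] != len(cur):
                raise AssertionError(f"count mismatch at stage {name}")
            if prev is not None and not cur <= prev:
                raise AssertionError(
                    f"survivors at {name} not nested in previous stage")
            prev = cur


# ------------------------------------------------------ regulatory score

REGULOME_ORDER = ("1a", "1b", "1c", "1d", "1e", "1f", "2a", "2b", "2c",
                  "3a", "3b", "4", "5", "6")
_REGULOME_RANK = {c: i + 1 for i, c in enumerate(REGULOME_ORDER)}


def regulome_rank(score_class: str) -> int:
    """Total order over regulatory score classes; classes through 4 carry
    enough regulatory evidence to keep, 5 and 6 are dropped."""
    try:
        return _REGULOME_RANK[score_class]
    except KeyError:
        raise InvalidAnnotationError(
            f"unknown regulatory score class {score_class!r}") from None


def regulome_keep(score_class: str, max_class: str = "4") -> bool:
    return regulome_rank(score_class) <= regulome_rank(max_class)


# --------------------------------------------------------- eQTL filter


def eqtl_filter_and_risk_allele(ann: SnvAnnotation, slc_direction: str,
                                tissue: str = "Lung", alpha: float = 0.05,
                                ) -> tuple[bool, str | None]:
    """Lung cis-eQTL filter with risk-allele inference.

    A variant passes when it has a significant eQTL entry for ``tissue``.
    The risk allele is the allele whose presence pushes expression toward
    the direction observed in the cancer group: the effect allele when the
    beta sign matches ``slc_direction`` (positive beta with 'up', negative
    with 'down'), otherwise the opposite allele. Significant entries that
    disagree about the risk allele are ambiguous and the variant is
    dropped (returns (False, "ambiguous")).
    """
    if slc_direction not in ("up", "down"):
        raise InvalidInputError(f"slc_direction must be up/down, "
                                f"got {slc_direction}")
    sig = [e for e in ann.eqtl if e.tissue == tissue and e.p < alpha]
    if not sig:
        return False, None
    calls = set()
    for e in sig:
        if e.beta == 0:
            calls.add("ambiguous")
            continue
        matches = (e.beta > 0) == (slc_direction == "up")
        other = ann.ref if e.effect_allele == ann.alt else ann.alt
        calls.add(e.effect_allele if matches else other)
    if len(calls) != 1 or "ambiguous" in calls:
        return False, "ambiguous"
    return True, calls.pop()


# --------------------------------------------------------- PWM scoring


def validate_pwm(pwm: np.ndarray) -> np.ndarray:
    pwm = np.asarray(pwm, dtype=float)
    if pwm.ndim != 2 or pwm.shape[1] != 4:
        raise InvalidMotifError("PWM must have shape (L, 4) in ACGT order")
    sums = pwm.sum(axis=1)
    if np.any(sums <= 0):
        raise InvalidMotifError("PWM has a zero column sum")
    return pwm / sums[:, None]


def _int_logodds(pwm: np.ndarray, background: np.ndarray,
                 step: float) -> np.ndarray:
    """Per-cell log2 odds on an integer grid of ``step`` log-odds units;
    zero-probability cells map to a sentinel (minimum int) meaning -inf."""
    with np.errstate(divide="ignore"):
        lo = np.log2(pwm / background[None, :])
    q = np.full(pwm.shape, np.iinfo(np.int64).min, dtype=np.int64)
    finite = np.isfinite(lo)
    q[finite] = np.round(lo[finite] / step).astype(np.int64)
    return q


def _window_score(q: np.ndarray, seq: str, offset: int) -> int | None:
    """Integer score of the motif placed at ``offset``; None when the
    window hits a zero-probability cell (score -inf)."""
    total = 0
    sentinel = np.iinfo(np.int64).min
    for i in range(q.shape[0]):
        v = q[i, _BASE_INDEX[seq[offset + i]]]
        if v == sentinel:
            return None
        total += int(v)
    return total


def score_distribution_tail(q: np.ndarray, background: np.ndarray,
                            threshold: int) -> float:
    """P(score of a random motif-length sequence >= threshold) under the
    background model, by exact DP convolution over the integer score grid.
    Sequences touching a zero-probability cell score -inf and never reach
    a finite threshold."""
    sentinel = np.iinfo(np.int64).min
    dist = np.array([1.0])
    offset = 0
    for i in range(q.shape[0]):
        vals = q[i]
        finite = vals != sentinel
        if not finite.any():
            return 0.0
        vmin, vmax = int(vals[finite].min()), int(vals[finite].max())
        pos = np.zeros(vmax - vmin + 1)
        for j in range(4):
            if finite[j]:
                pos[int(vals[j]) - vmin] += background[j]
        dist = np.convolve(dist, pos)
        offset += vmin
    start = threshold - offset
    if start <= 0:
        return float(dist.sum())
    if start >= len(dist):
        return 0.0
    return float(dist[start:].sum())


def pwm_impact_score(context: str, ref: str, alt: str, pwm: np.ndarray,
                     background=None, alpha_impact: float = 0.001,
                     step: float = 0.01, snv_index: int | None = None,
                     tf: str = "", pwm_id: str = "",
                     tf_expressed_in_lung: bool = True) -> TfbsImpact:
    """Allele-specific binding impact of a variant on one motif.

    The context window (>= motif length) is scanned with each allele
    substituted at ``snv_index`` (default: the window center); the score
    of an allele is the best log-odds over all motif placements containing
    the variant. ``p_impact`` for an allele is the exact probability that
    a random motif-length background sequence scores at least that
    allele's best score. Direction is 'gain' when the alternate allele
    scores higher and its match is significant (p_impact < alpha_impact),
    'loss' when the reference allele scores higher and significant, else
    'none'. The reported p_impact belongs to the better-scoring allele.
    """
    pwm = validate_pwm(pwm)
    L = pwm.shape[0]
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    background = background / background.sum()
    if len(context) < L:
        raise InvalidInputError("context window shorter than the motif")
    c = len(context) // 2 if snv_index is None else snv_index
    if not 0 <= c < len(context):
        raise InvalidInputError("snv_index outside the context window")
    for allele in (ref, alt):
        if allele not in _BASE_INDEX:
            raise InvalidInputError(f"allele {allele!r} is not a base")

    q = _int_logodds(pwm, background, step)
    lo_off = max(0, c - L + 1)
    hi_off = min(len(context) - L, c)
    if lo_off > hi_off:
        raise InvalidInputError("no motif placement contains the variant")

    def best(allele: str) -> int | None:
        seq = context[:c] + allele + context[c + 1:]
        scores = [_window_score(q, seq, o) for o in range(lo_off, hi_off + 1)]
        finite = [s for s in scores if s is not None]
        return max(finite) if finite else None

    b_ref, b_alt = best(ref), best(alt)

    def pval(b: int | None) -> float:
        return 1.0 if b is None else score_distribution_tail(q, background, b)

    p_ref, p_alt = pval(b_ref), pval(b_alt)
    neg_inf = float("-inf")
    s_ref = neg_inf if b_ref is None else b_ref * step
    s_alt = neg_inf if b_alt is None else b_alt * step

    direction = "none"
    if s_alt > s_ref and p_alt < alpha_impact:
        direction = "gain"
    elif s_alt < s_ref and p_ref < alpha_impact:
        direction = "loss"
    p_impact = p_alt if s_alt > s_ref else p_ref
    return TfbsImpact(tf=tf, pwm_id=pwm_id, score_ref=s_ref, score_alt=s_alt,
                      direction=direction, p_impact=p_impact,
                      tf_expressed_in_lung=tf_expressed_in_lung)


# --------------------------------------------------- chromatin domains

# 25-state chromatin model vocabulary (core-marks + imputed model labels)
CHROMATIN_STATES = (
    "Active TSS", "Promoter Upstream of TSS", "Promoter Downstream of TSS 1",
    "Promoter Downstream of TSS 2", "Transcribed - 5' preferential",
    "Strong transcription", "Transcribed - 3' preferential",
    "Weak transcription", "Transcribed & regulatory (Prom/Enh)",
    "Transcribed 5' preferential and Enh",
    "Transcribed 3' preferential and Enh", "Transcribed and Weak Enhancer",
    "Active Enhancer 1", "Active Enhancer 2", "Active Enhancer Flank",
    "Weak Enhancer 1", "Weak Enhancer 2",
    "Primary H3K27ac possible Enhancer", "Primary DNase site",
    "ZNF genes & repeats", "Heterochromatin", "Poised Promoter",
    "Bivalent Promoter", "Repressed Polycomb", "Quiescent", "Quiescent/Low",
)
_STATE_SET = {s.lower() for s in CHROMATIN_STATES}


def chromatin_domain_class(state_label: str) -> str:
    """Collapse a 25-state chromatin label to enhancer / promoter /
    repressed_or_insulator."""
    if state_label.lower() not in _STATE_SET:
        raise InvalidAnnotationError(
            f"unknown chromatin state {state_label!r}")
    low = state_label.lower()
    if "enhancer" in low or "h3k27ac" in low:
        return "enhancer"
    if "tss" in low or "promoter" in low:
        return "promoter"
    return "repressed_or_insulator"


# ----------------------------------------------------------- cascade


def global_maf(ann: SnvAnnotation) -> float:
    """Minor-allele frequency of the pooled (population-averaged) alternate
    or risk allele frequency."""
    if not ann.pop_freq:
        raise MissingAnnotationError(f"{ann.rsid}: no population frequencies")
    f = float(np.mean(list(ann.pop_freq.values())))
    return min(f, 1.0 - f)


def best_lung_eqtl_p(ann: SnvAnnotation, tissue: str = "Lung") -> float:
    ps = [e.p for e in ann.eqtl if e.tissue == tissue]
    return min(ps) if ps else 1.0


class CascadeResult(NamedTuple):
    state: CascadeState
    survivors: list[SnvAnnotation]   # risk_allele set where inferred
    polymorphic: set[str]            # survivors with global MAF > threshold
    shortlist: set[str]              # polymorphic promoter variants with
    # a lung eQTL below the shortlist threshold
    tfbs_summary: pd.DataFrame       # per-survivor gain/loss annotation


def run_cascade(snvs: Iterable[SnvAnnotation],
                slc_direction: dict[str, str],
                thresholds: Thresholds | None = None,
                tfbs_filter: bool = False) -> CascadeResult:
    """Run the ordered filters and derive the genotyping shortlist.

    Stage order: DHS membership, regulatory-evidence flag, regulatory
    score class, lung cis-eQTL with risk-allele inference, lung DHS
    presence, then (annotative by default) predicted TF-binding impact by
    a lung-expressed factor. Variants whose gene lacks a cancer-group
    expression direction cannot orient a risk allele and drop at the eQTL
    stage.
    """
    th = thresholds or Thresholds()
    anns = list(snvs)
    state = CascadeState(stage_names=["input"], survivors_per_stage={},
                         counts={})
    current = {a.rsid: a for a in anns}
    if len(current) != len(anns):
        raise InvalidInputError("duplicate rsids in cascade input")
    state.survivors_per_stage["input"] = set(current)
    state.counts["input"] = len(current)

    def apply_stage(name: str, keep) -> None:
        nonlocal current
        current = {r: a for r, a in current.items() if keep(a)}
        state.stage_names.append(name)
        state.survivors_per_stage[name] = set(current)
        state.counts[name] = len(current)

    apply_stage("dhs", lambda a: a.in_dhs)
    apply_stage("regulatory", lambda a: a.is_regulatory)
    apply_stage("regulome",
                lambda a: regulome_keep(a.score_class, th.regulome_max_class))

    def eqtl_keep(a: SnvAnnotation) -> bool:
        direction = slc_direction.get(a.gene)
        if direction is None:
            return False
        ok, allele = eqtl_filter_and_risk_allele(a, direction,
                                                 alpha=th.eqtl_alpha)
        if ok:
            a.risk_allele = allele
        return ok

    apply_stage("eqtl", eqtl_keep)
    apply_stage("lung_dhs", lambda a: a.lung_dhs_present)

    def has_lung_tf_impact(a: SnvAnnotation) -> bool:
        return any(t.direction != "none" and t.tf_expressed_in_lung
                   for t in a.tfbs_impacts)

    if tfbs_filter:
        apply_stage("tfbs", has_lung_tf_impact)

    survivors = list(current.values())
    tfbs_rows = [(a.rsid, t.tf, t.direction, t.p_impact,
                  t.tf_expressed_in_lung)
                 for a in survivors for t in a.tfbs_impacts]
    tfbs_summary = pd.DataFrame(
        tfbs_rows, columns=["rsid", "tf", "direction", "p_impact",
                            "tf_expressed_in_lung"])

    polymorphic = {a.rsid for a in survivors if global_maf(a) > th.maf_min}
    shortlist = {
        a.rsid for a in survivors
        if a.rsid in polymorphic
        and chromatin_domain_class(a.chromatin_state) == "promoter"
        and best_lung_eqtl_p(a) < th.shortlist_alpha
    }
    state.check_nested()
    return CascadeResult(state, survivors, polymorphic, shortlist,
                         tfbs_summary)


# ------------------------------------------------------------ I/O glue


def annotations_from_frame(df: pd.DataFrame,
                           in_dhs_rsids: set[str] | None = None,
                           ) -> list[SnvAnnotation]:
    """Build annotation objects from a flat table with JSON-encoded nested
    columns (eqtl, cancer_eqtl, tfbs, pop_freq). DHS membership comes from
    ``in_dhs_rsids`` when given, else from an ``in_dhs`` column."""
    required = {"rsid", "gene", "ref", "alt", "is_regulatory", "score_class",
                "eqtl", "chromatin_state", "lung_dhs_present", "pop_freq"}
    missing = required - set(df.columns)
    if missing:
        raise MissingAnnotationError(f"missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        eqtl = [EqtlEntry(**e) for e in json.loads(row.eqtl)]
        cancer = [CancerEqtl(**e) for e in json.loads(row.cancer_eqtl)] \
            if "cancer_eqtl" in df.columns else []
        tfbs = [TfbsImpact(**t) for t in json.loads(row.tfbs)] \
            if "tfbs" in df.columns else []
        if in_dhs_rsids is not None:
            in_dhs = row.rsid in in_dhs_rsids
        else:
            in_dhs = bool(row.in_dhs) if "in_dhs" in df.columns else False
        out.append(SnvAnnotation(
            rsid=row.rsid, gene=row.gene, ref=row.ref, alt=row.alt,
            is_regulatory=bool(row.is_regulatory),
            score_class=str(row.score_class), eqtl=eqtl, cancer_eqtl=cancer,
            chromatin_state=row.chromatin_state,
            lung_dhs_present=bool(row.lung_dhs_present),
            tfbs_impacts=tfbs, pop_freq=json.loads(row.pop_freq),
            in_dhs=in_dhs))
    return out


def bh_fdr(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values, used for the cancer-cohort
    cis-eQTL confirmation."""
    p = np.asarray(list(pvalues), dtype=float)
    n = len(p)
    if n == 0:
        return np.empty(0)
    order = np.argsort(p)
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = running
    return q
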
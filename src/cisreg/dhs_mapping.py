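"""Expression-correlated DHS selection and variant-to-interval assignment.

For each DNase I hypersensitive site (DHS) near a gene, the statistic is
the Pearson correlation across samples between the site's normalized DNase
signal and the gene's expression. Significance comes from a permutation
null: the same expression vector is correlated against a seeded random
sample of DHS signal vectors drawn from *other* chromosomes, and the
two-sided (absolute-correlation) exceedance fraction is reported with the
add-one correction so p is never exactly zero.

Intervals are 0-based half-open (BED convention); variant positions are
1-based (VCF convention). A variant at 1-based position p lies in
[start, end) iff start <= p-1 < end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .errors import (InvalidInputError, MissingAnnotationError,
                     UndefinedCorrelationError)


@dataclass
class DhsRegion:
    chrom: str
    start: int
    end: int
    gene: str
    signal: np.ndarray = field(default_factory=lambda: np.empty(0))
    r: float | None = None
    p_perm: float | None = None
    correlation_sign: str | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise InvalidInputError(
                f"interval start must be < end: {self.start}..{self.end}")
        self.signal = np.asarray(self.signal, dtype=float)

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class SnvRecord:
    rsid: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    assigned_dhs: DhsRegion | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise InvalidInputError(f"pos must be >= 1, got {self.pos}")


def _masked(signal: np.ndarray, expression: np.ndarray,
            floor_quantile: float) -> np.ndarray:
    """Row mask keeping samples at or above both per-vector floors."""
    fs = np.quantile(signal, floor_quantile)
    fe = np.quantile(expression, floor_quantile)
    return (signal >= fs) & (expression >= fe)


def dhs_expression_correlation(signal, expression, null_pool,
                               n_perm: int = 10_000, seed: int = 0,
                               floor_quantile: float = 0.10,
                               ) -> tuple[float, float]:
    """Pearson r between DNase signal and expression, with permutation p.

    Samples below the per-vector minimum floors (default: each vector's
    10th percentile) are masked before computing r; the same row mask is
    applied to the null vectors so the null and observed statistics are
    computed on identical samples. The permutation p-value is

        (1 + #{null d: |corr(d, expression)| >= |r|}) / (1 + m)

    over a seeded sample of m = min(n_perm, |null_pool|) null DHSs drawn
    without replacement, whose signal vectors the caller guarantees come
    from chromosomes other than the query's.
    """
    signal = np.asarray(signal, dtype=float)
    expression = np.asarray(expression, dtype=float)
    if signal.shape != expression.shape or signal.ndim != 1:
        raise InvalidInputError("signal and expression must be equal-length "
                                "1-D vectors")
    if len(signal) < 3:
        raise InvalidInputError("need at least 3 samples")
    mask = _masked(signal, expression, floor_quantile)
    s, e = signal[mask], expression[mask]
    if len(s) < 3 or np.ptp(s) == 0 or np.ptp(e) == 0:
        raise UndefinedCorrelationError(
            "constant or near-empty vectors after floor masking")
    r = float(stats.pearsonr(s, e).statistic)

    pool = [np.asarray(v, dtype=float) for v in null_pool]
    rng = np.random.default_rng(seed)
    m = min(n_perm, len(pool))
    idx = rng.choice(len(pool), size=m, replace=False) if m else np.array([],
                                                                          int)
    hits = 0
    for i in idx:
        v = pool[i][mask]
        if np.ptp(v) == 0:
            continue
        if abs(stats.pearsonr(v, e).statistic) >= abs(r) - 1e-12:
            hits += 1
    p_perm = (1 + hits) / (1 + m)
    return r, p_perm


def select_candidate_dhs(gene: str, regions: list[DhsRegion],
                         tss: dict[str, int], k: int = 10,
                         alpha: float = 0.05,
                         window_kb: int = 100) -> list[DhsRegion]:
    """Top-k expression-correlated DHSs for a gene.

    Keeps regions whose midpoint lies within ``window_kb`` of the gene's
    TSS and whose permutation p is below ``alpha``, ranks by |r|
    descending (ties broken by genomic coordinate for determinism), and
    returns at most k, each labeled with its correlation sign.
    """
    if gene not in tss:
        raise MissingAnnotationError(f"TSS unknown for gene {gene}")
    t = tss[gene]
    window = window_kb * 1000
    eligible = []
    for reg in regions:
        if reg.gene != gene:
            continue
        if reg.r is None or reg.p_perm is None:
            raise MissingAnnotationError(
                f"region {reg.chrom}:{reg.start}-{reg.end} lacks r/p_perm")
        if abs(reg.midpoint - t) <= window and reg.p_perm < alpha:
            eligible.append(reg)
    eligible.sort(key=lambda x: (-abs(x.r), x.chrom, x.start))
    out = []
    for reg in eligible[:k]:
        out.append(replace(
            reg, correlation_sign="positive" if reg.r >= 0 else "negative"))
    return out


def map_snvs_to_dhs(snvs: list[SnvRecord], regions: list[DhsRegion],
                    ) -> tuple[list[SnvRecord], dict[str, int]]:
    """Assign variants to containing DHS intervals (half-open containment).

    A variant overlapping several intervals yields one output record per
    interval. Returns the assigned records plus counts of assignments to
    positively and negatively correlated DHSs (unsigned regions counted
    under 'unsigned').
    """
    by_chrom: dict[str, list[DhsRegion]] = {}
    for reg in regions:
        by_chrom.setdefault(reg.chrom, []).append(reg)
    assigned: list[SnvRecord] = []
    counts = {"positive": 0, "negative": 0, "unsigned": 0}
    for snv in snvs:
        hit = False
        for reg in by_chrom.get(snv.chrom, ()):
            if reg.start <= snv.pos - 1 < reg.end:
                assigned.append(replace(snv, assigned_dhs=reg))
                counts[reg.correlation_sign or "unsigned"] += 1
                hit = True
        if not hit:
            assigned.append(replace(snv, assigned_dhs=None))
    return assigned, counts
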
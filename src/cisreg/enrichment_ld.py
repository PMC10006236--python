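"""Annotation enrichment against sampled variant universes, and LD tools.

The enrichment design: draw a random universe of variants from the pooled
TSS +/- 100 kb regions of the candidate genes, cross-tabulate an annotation
(regulatory flag, score class, eQTL status, catalog membership) between the
study set and the universe, and test the 2x2 with Fisher's exact test. The
odds ratio is the transparent sample cross-product (a*d)/(b*c) with the
Haldane-Anscombe +0.5 correction when any cell is zero, and the 95% CI is
the Woolf log-normal interval.

LD expansion collects all partners at r-squared >= 0.8 (a variant is its
own partner by convention), and transitive association evidence flags a
variant whose LD block intersects a catalog of reported associations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateTableError, InsufficientPoolError, \
    InvalidInputError


@dataclass(frozen=True)
class Contingency2x2:
    """a = positives in group 1, b = remainder of group 1,
    c = positives in group 2, d = remainder of group 2."""
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InvalidInputError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise DegenerateTableError("all cells are zero")


@dataclass
class EnrichmentResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str


def _cross_product_or(t: Contingency2x2) -> tuple[float, float, float, str]:
    """Cross-product OR with Woolf CI; +0.5 to every cell iff any is zero."""
    a, b, c, d = t.a, t.b, t.c, t.d
    method = "cross-product"
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        method = "cross-product (Haldane-Anscombe)"
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    return or_, math.exp(math.log(or_) - z * se), \
        math.exp(math.log(or_) + z * se), method


def fisher_2x2(t: Contingency2x2) -> EnrichmentResult:
    """Two-sided Fisher exact p (sum of hypergeometric outcomes no more
    probable than the observed table) with the cross-product odds ratio
    and Woolf 95% CI."""
    p = float(stats.fisher_exact([[t.a, t.b], [t.c, t.d]],
                                 alternative="two-sided")[1])
    or_, lo, hi, method = _cross_product_or(t)
    return EnrichmentResult(odds_ratio=or_, ci_low=lo, ci_high=hi,
                            p_value=p, method=f"fisher-exact/{method}")


def sample_universe(pool: Sequence[str], n: int, seed: int) -> set[str]:
    """Seeded uniform sample of n distinct variant ids without replacement
    from a pool built from the candidate genes' TSS +/- 100 kb regions."""
    pool = list(pool)
    if n > len(pool):
        raise InsufficientPoolError(
            f"requested {n} from a pool of {len(pool)}")
    if n < 0:
        raise InvalidInputError("n must be >= 0")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return {pool[i] for i in idx}


def ld_expand(seeds: Iterable[str], pairs: Iterable[tuple[str, str, float]],
              r2_min: float = 0.8) -> dict[str, set[str]]:
    """All LD partners of each seed at r-squared >= ``r2_min`` (inclusive).
    Pairs are treated symmetrically; each seed partners itself (r2 = 1)."""
    if not 0.0 <= r2_min <= 1.0:
        raise InvalidInputError("r2_min must be in [0, 1]")
    seeds = list(seeds)
    adjacency: dict[str, set[str]] = {}
    for a, b, r2 in pairs:
        if not 0.0 <= r2 <= 1.0:
            raise InvalidInputError(f"r2 out of [0,1] for ({a},{b}): {r2}")
        if r2 >= r2_min:
            adjacency.setdefault(a, set()).add(b)
            adjacency.setdefault(b, set()).add(a)
    return {s: {s} | adjacency.get(s, set()) for s in seeds}


def transitive_enrichment(seed_partners: Mapping[str, set[str]],
                          catalog: set[str],
                          universe_partners: Mapping[str, set[str]],
                          ) -> tuple[dict[str, bool], EnrichmentResult]:
    """Flag seeds whose LD block touches the association catalog and test
    whether catalog hits are enriched among seed partners relative to the
    partners of a random variant universe."""
    flags = {s: bool(partners & catalog)
             for s, partners in seed_partners.items()}
    seed_union = set().union(*seed_partners.values()) if seed_partners \
        else set()
    uni_union = set().union(*universe_partners.values()) \
        if universe_partners else set()
    a = len(seed_union & catalog)
    b = len(seed_union) - a
    c = len(uni_union & catalog)
    d = len(uni_union) - c
    result = fisher_2x2(Contingency2x2(a, b, c, d))
    return flags, result


def haplotype_r2(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """Squared allelic correlation between two phased haplotype vectors
    (0/1 coded). Provided for the synthetic generator's internal
    consistency; real r2 tables are accepted as input."""
    a = np.asarray(hap_a, dtype=float)
    b = np.asarray(hap_b, dtype=float)
    if a.shape != b.shape:
        raise InvalidInputError("haplotype vectors differ in length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)
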
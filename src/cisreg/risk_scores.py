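"""Risk-allele dosage and the unweighted genetic risk score (uGRS).

The uGRS of a subject is the plain sum of risk-allele copies over the
prioritized variant panel — an integer in [0, 2 x number of loci]. Its
population mean equals 2 x the sum of risk-allele frequencies, which makes
population ranking a direct function of the frequency vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .errors import (EmptyInputError, InvalidGenotypeError,
                     MissingGenotypeError)


@dataclass
class RiskPanel:
    """Ordered loci with their risk alleles and optional per-population
    risk-allele frequencies keyed by (population, rsid)."""
    loci: list[tuple[str, str]]  # (rsid, risk_allele)
    alleles: dict[str, tuple[str, str]] = field(default_factory=dict)
    freqs: dict[tuple[str, str], float] = field(default_factory=dict)


def parse_genotype(genotype) -> tuple[str, str] | None:
    """Accepts 'A/G', 'A|G', ('A', 'G'), or missing (None/NaN)."""
    if genotype is None or (isinstance(genotype, float) and
                            pd.isna(genotype)):
        return None
    if isinstance(genotype, str):
        sep = "|" if "|" in genotype else "/"
        parts = genotype.split(sep)
        if len(parts) != 2:
            raise InvalidGenotypeError(f"cannot parse genotype {genotype!r}")
        return parts[0], parts[1]
    a, b = genotype
    return a, b


def risk_dosage(genotype, risk_allele: str,
                alphabet: tuple[str, str] | None = None) -> int:
    """Copies of the risk allele in an unordered genotype (0, 1 or 2)."""
    pair = parse_genotype(genotype)
    if pair is None:
        raise MissingGenotypeError("genotype is missing")
    if alphabet is not None:
        bad = [a for a in pair if a not in alphabet]
        if bad:
            raise InvalidGenotypeError(
                f"allele(s) {bad} outside locus alphabet {alphabet}")
    return sum(1 for a in pair if a == risk_allele)


def ugrs_subject(genotypes: Mapping[str, object], panel: RiskPanel,
                 impute_missing: bool = False,
                 population: str | None = None) -> float:
    """Sum of risk-allele dosages over the panel.

    Missing genotypes raise by default; with ``impute_missing`` they
    contribute the expected dosage 2 x risk-allele frequency of
    ``population`` (which makes the score fractional)."""
    total: float = 0
    for rsid, risk_allele in panel.loci:
        geno = genotypes.get(rsid)
        if parse_genotype(geno) is None:
            if not impute_missing:
                raise MissingGenotypeError(
                    f"locus {rsid} not genotyped and imputation disabled")
            if population is None or (population, rsid) not in panel.freqs:
                raise MissingGenotypeError(
                    f"no frequency available to impute {rsid}")
            total += 2.0 * panel.freqs[(population, rsid)]
            continue
        total += risk_dosage(geno, risk_allele, panel.alleles.get(rsid))
    return total


def population_ugrs_ranking(panel: RiskPanel,
                            genotype_panels: Mapping[str, pd.DataFrame],
                            ) -> pd.DataFrame:
    """Mean subject uGRS per population, sorted descending (ties broken
    alphabetically). Empty populations are excluded."""
    rows = []
    for pop in genotype_panels:
        table = genotype_panels[pop]
        if len(table) == 0:
            continue
        scores = [
            ugrs_subject(row, panel)
            for row in table.to_dict("records")
        ]
        rows.append((pop, sum(scores) / len(scores), len(scores)))
    if not rows:
        raise EmptyInputError("no non-empty populations")
    out = pd.DataFrame(rows, columns=["population", "mean_ugrs", "n"])
    return out.sort_values(["mean_ugrs", "population"],
                           ascending=[False, True], ignore_index=True)


def cooccurrence_summary(genotypes: pd.DataFrame,
                         panel: RiskPanel) -> pd.DataFrame:
    """Per-subject risk-allele dosage per locus plus the uGRS total."""
    records = genotypes.to_dict("records")
    rows = []
    for rec in records:
        dosages = {rsid: risk_dosage(rec[rsid], risk)
                   for rsid, risk in panel.loci}
        dosages["ugrs"] = sum(dosages.values())
        if "id" in rec:
            dosages["id"] = rec["id"]
        rows.append(dosages)
    return pd.DataFrame(rows)
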
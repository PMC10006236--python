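"""Reciprocal-expression candidate-gene prioritization.

Genes are screened across two comparisons: Set A (healthy smokers vs
healthy non-smokers) and Set B (smokers with lung cancer vs healthy
smokers). A gene's per-comparison status (up / down / no_change) feeds a
category assignment:

* (a) up in Set A, down in Set B — induced by smoke, lost in cancer;
* (b) down in Set A, up in Set B — the reverse pattern, biologically
  implausible as a susceptibility signature for DNA-repair genes (a higher
  repair capacity should not predispose), so (b) is excluded for the DRG
  pathway;
* (c) no change in Set A, down in Set B.

Anything else, including inconclusive or missing comparisons, is excluded.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable

import pandas as pd

from .errors import AmbiguousInputError, InvalidInputError

STATUSES = ("up", "down", "no_change", "inconclusive")
RECORD_COLUMNS = ("gene", "pathway", "comparison", "fold_change",
                  "direction", "p_value")


def classify_group_status(fold_change: float, direction: str, p_value: float,
                          fc_threshold: float = 1.5,
                          alpha: float = 0.05) -> str:
    """Call a comparison up/down/no_change from an oriented fold change.

    ``fold_change`` is the larger-group mean over the smaller-group mean
    (always >= 1); ``direction`` says which way it points.
    """
    if fold_change < 1:
        raise InvalidInputError(
            f"fold_change must be >= 1 (oriented ratio), got {fold_change}")
    if direction not in ("up", "down"):
        raise InvalidInputError(f"direction must be up/down, got {direction}")
    if not 0.0 <= p_value <= 1.0:
        raise InvalidInputError(f"p_value out of [0,1]: {p_value}")
    if fold_change >= fc_threshold and p_value < alpha:
        return direction
    return "no_change"


def assign_category(setA_status: str, setB_status: str, pathway: str) -> str:
    """Map the (Set A, Set B) status pair to a selection category."""
    if setA_status not in STATUSES or setB_status not in STATUSES:
        raise InvalidInputError(
            f"unknown status pair ({setA_status}, {setB_status})")
    if "inconclusive" in (setA_status, setB_status):
        return "excluded"
    pair = (setA_status, setB_status)
    if pair == ("up", "down"):
        return "a"
    if pair == ("down", "up"):
        return "excluded" if pathway == "DRG" else "b"
    if pair == ("no_change", "down"):
        return "c"
    return "excluded"


def consensus_status(statuses: Iterable[str], min_concordant: int = 3) -> str:
    """Optional pre-aggregation across cell types: majority direction,
    requiring more than two concordant calls, else inconclusive."""
    counts = Counter(s for s in statuses if s in ("up", "down"))
    if not counts:
        return "no_change"
    status, k = counts.most_common(1)[0]
    if k >= min_concordant and k > sum(counts.values()) - k:
        return status
    return "inconclusive"


def select_genes(records: pd.DataFrame, fc_threshold: float = 1.5,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Apply per-comparison status calls and category rules gene by gene.

    ``records`` needs columns gene, pathway, comparison (SetA/SetB),
    fold_change, direction, p_value; at most one row per (gene,
    comparison). Genes missing either comparison are inconclusive and
    excluded. Output is sorted by gene so the result is invariant to input
    row order.
    """
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise InvalidInputError(f"missing columns: {sorted(missing)}")
    dupes = records.duplicated(["gene", "comparison"])
    if dupes.any():
        bad = records.loc[dupes, "gene"].unique()
        raise AmbiguousInputError(
            f"duplicate (gene, comparison) records for {list(bad)[:5]}")

    calls = []
    for gene, sub in records.groupby("gene", sort=True):
        pathway = sub.pathway.iloc[0]
        status = {}
        for comparison in ("SetA", "SetB"):
            row = sub[sub.comparison == comparison]
            if row.empty:
                status[comparison] = "inconclusive"
            else:
                r = row.iloc[0]
                status[comparison] = classify_group_status(
                    r.fold_change, r.direction, r.p_value, fc_threshold,
                    alpha)
        category = assign_category(status["SetA"], status["SetB"], pathway)
        calls.append((gene, pathway, status["SetA"], status["SetB"],
                      category, category in ("a", "b", "c")))
    return pd.DataFrame(
        calls, columns=["gene", "pathway", "setA_status", "setB_status",
                        "category", "selected"],
    )


def slc_directions(calls: pd.DataFrame) -> dict[str, str]:
    """Per-gene expression direction in the cancer group relative to
    healthy smokers, for selected genes — the orientation used downstream
    for risk-allele inference."""
    out = {}
    for _, row in calls[calls.selected].iterrows():
        if row.setB_status in ("up", "down"):
            out[row.gene] = row.setB_status
    return out
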
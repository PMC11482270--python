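"""Differential-expression filtering and cell-type overrepresentation.

A differential-expression table (gene, signed linear fold change, adjusted
p) is filtered to up- / down- / any-regulated lists (adjusted p < 0.05,
|FC| >= 1.5; the FC bound is inclusive, the p bound strict).  Each list is
tested for overrepresentation of cell-type marker gene sets with an
upper-tail hypergeometric test within a gene universe, BH-corrected across
sets, and the gene-by-set overlaps are emitted as a binary matrix.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigurationError
from .markers import MarkerGeneSetCollection

logger = logging.getLogger(__name__)

DIRECTIONS = ("up", "down", "both")


def _check_de_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"gene", "fold_change", "adjusted_p"}
    missing = required - set(table.columns)
    if missing:
        raise ConfigurationError(f"DE table lacks columns {sorted(missing)}")
    if table["gene"].duplicated().any():
        raise ConfigurationError("DE table has duplicate gene symbols")
    return table


def filter_de(
    table: pd.DataFrame,
    direction: str = "both",
    fc_min: float = 1.5,
    alpha: float = 0.05,
) -> list[str]:
    """Select significantly regulated genes from a DE table.

    ``fold_change`` is a signed linear fold change (+2 = doubled, -2 =
    halved).  ``up``: FC >= +fc_min; ``down``: FC <= -fc_min; ``both``:
    |FC| >= fc_min — all additionally requiring adjusted_p < alpha.
    """
    table = _check_de_table(table)
    if direction not in DIRECTIONS:
        raise ConfigurationError(f"direction must be one of {DIRECTIONS}")
    if fc_min < 1:
        raise ConfigurationError("fc_min must be >= 1 (linear fold change)")
    sig = table["adjusted_p"] < alpha
    fc = table["fold_change"]
    if direction == "up":
        keep = sig & (fc >= fc_min)
    elif direction == "down":
        keep = sig & (fc <= -fc_min)
    else:
        keep = sig & (fc.abs() >= fc_min)
    return table.loc[keep, "gene"].tolist()


def default_universe(
    de_genes: list[str] | pd.Series, sets: MarkerGeneSetCollection
) -> list[str]:
    """Universe = DE-table genes intersected with the union of set genes."""
    set_union = set(sets.universe)
    return [g for g in de_genes if g in set_union]


def overrepresentation(
    query: list[str],
    sets: MarkerGeneSetCollection,
    universe: list[str],
    alpha: float = 0.05,
    correction: str = "bh",
) -> pd.DataFrame:
    """Upper-tail hypergeometric test of each gene set against a query list.

    With universe size N, set size K (after intersection with the
    universe), query size n and overlap k, the p value is
    P(X >= k) for X ~ Hypergeometric(N, K, n).  Correction across sets is
    BH by default (``correction='bonferroni'`` available).
    """
    universe_set = set(universe)
    if not universe_set:
        raise ConfigurationError("empty gene universe")
    query_in = [g for g in dict.fromkeys(query) if g in universe_set]
    dropped = len(set(query)) - len(query_in)
    if dropped:
        logger.warning("%d query genes outside the universe were dropped", dropped)
    n = len(query_in)
    N = len(universe_set)
    query_set = set(query_in)

    rows = []
    for name, gs in sets.sets.items():
        members = set(gs.genes) & universe_set
        K = len(members)
        overlap = sorted(query_set & members)
        k = len(overlap)
        p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n)) if n else 1.0
        rows.append({
            "set": name,
            "overlap_count": k,
            "overlap_genes": ",".join(overlap),
            "universe_size": N,
            "set_size_in_universe": K,
            "query_size": n,
            "p_value": min(p, 1.0),
        })
    result = pd.DataFrame(rows).set_index("set")
    method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(correction)
    if method is None:
        raise ConfigurationError(f"unknown correction {correction!r}")
    result["adjusted_p"] = multipletests(result["p_value"], method=method)[1]
    result["significant"] = result["adjusted_p"] < alpha
    return result


def overlap_matrix(
    query: list[str], sets: MarkerGeneSetCollection
) -> pd.DataFrame:
    """Binary query-gene x set membership matrix.

    Genes overlapping no set are omitted, so column sums equal the per-set
    overlap counts and the row set matches what the heatmaps display.
    """
    names = sets.names
    members = {name: set(sets[name].genes) for name in names}
    rows = []
    index = []
    for g in dict.fromkeys(query):
        row = [1 if g in members[name] else 0 for name in names]
        if any(row):
            rows.append(row)
            index.append(g)
    return pd.DataFrame(
        np.asarray(rows, dtype=int).reshape(len(index), len(names)),
        index=pd.Index(index, name="gene"),
        columns=names,
    )


def capitalize_mouse(symbols: list[str]) -> list[str]:
    """Map UPPER-case (human-style) symbols to Title case (mouse-style)."""
    return [s[:1].upper() + s[1:].lower() if s else s for s in symbols]
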
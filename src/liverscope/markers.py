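"""One-vs-rest marker gene selection and GMT gene-set serialization.

For every cell type, each gene is compared between cells of that type and
all other cells with a two-sided Wilcoxon rank-sum test (exact enumeration
when both groups have at most 8 cells and no ties; a tie-corrected normal
approximation otherwise), with Benjamini-Hochberg FDR correction across
genes within the cell type.  Marker sets keep genes with adjusted p < 0.05
and a linear fold change >= 1.5, ordered by decreasing fold change and
truncated to the top 200, then written to a standard GMT file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .exceptions import FormatError, NormalizationError
from .reference_prep import ReferenceCellAtlas

logger = logging.getLogger(__name__)

FC_PSEUDOCOUNT = 1e-8
EXACT_MAX_GROUP = 8


def normalize_reference_for_markers(
    atlas: ReferenceCellAtlas,
    method: str = "library-median",
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-cell scaling normalization of the reference counts.

    ``library-median`` rescales each cell so its library equals the median
    library size (a simple stand-in for pooled size-factor methods);
    ``none`` returns raw counts; ``factors`` divides by user-supplied
    per-cell size factors.
    """
    counts = atlas.counts.astype(float)
    if method == "none":
        return counts
    if method == "factors":
        if size_factors is None:
            raise ValueError("method='factors' requires size_factors")
        factors = size_factors.reindex(counts.columns)
        if factors.isna().any() or (factors <= 0).any():
            raise NormalizationError("size factors missing or non-positive")
        return counts / factors
    if method != "library-median":
        raise ValueError(f"unknown normalization method {method!r}")
    libs = counts.sum(axis=0)
    zero = libs[libs <= 0]
    if len(zero):
        raise NormalizationError(f"cells with zero library size: {list(zero.index)[:5]}")
    return counts / libs * float(np.median(libs))


def _exact_or_asymptotic(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p for one gene: exact for small tie-free groups."""
    if (
        len(x) <= EXACT_MAX_GROUP
        and len(y) <= EXACT_MAX_GROUP
        and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    ):
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def rank_markers(
    norm_expr: pd.DataFrame,
    cell_type: pd.Series,
    eps: float = FC_PSEUDOCOUNT,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon test and fold change for every (gene, type).

    Returns a tidy frame with columns ``gene``, ``cell_type``,
    ``fold_change`` (linear ratio of mean normalized expression, type vs
    rest, with pseudocount ``eps``), ``p_value`` and ``adjusted_p``
    (BH across genes within each cell type).  Cell types with fewer than
    2 cells (or leaving fewer than 2 in the rest) are skipped.
    """
    cell_type = cell_type.reindex(norm_expr.columns)
    expr = norm_expr.to_numpy(dtype=float)
    genes = norm_expr.index.to_numpy()
    frames = []
    for ct in sorted(pd.unique(cell_type.dropna())):
        in_mask = (cell_type == ct).to_numpy()
        n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
        if n_in < 2 or n_out < 2:
            logger.warning("cell type %r skipped: %d vs %d cells", ct, n_in, n_out)
            continue
        x = expr[:, in_mask]
        y = expr[:, ~in_mask]
        if n_in <= EXACT_MAX_GROUP and n_out <= EXACT_MAX_GROUP:
            pvals = np.array([
                _exact_or_asymptotic(x[g], y[g]) for g in range(expr.shape[0])
            ])
        else:
            pvals = scipy.stats.mannwhitneyu(
                x, y, axis=1, alternative="two-sided", method="asymptotic"
            ).pvalue
        mean_in = x.mean(axis=1)
        mean_out = y.mean(axis=1)
        fc = (mean_in + eps) / (mean_out + eps)
        adj = multipletests(pvals, method="fdr_bh")[1]
        frames.append(pd.DataFrame({
            "gene": genes,
            "cell_type": ct,
            "fold_change": fc,
            "p_value": pvals,
            "adjusted_p": adj,
        }))
    if not frames:
        return pd.DataFrame(
            columns=["gene", "cell_type", "fold_change", "p_value", "adjusted_p"]
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str]


@dataclass
class MarkerGeneSetCollection:
    """Ordered, named gene lists, one per cell type."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    @property
    def universe(self) -> list[str]:
        seen: dict[str, None] = {}
        for gs in self.sets.values():
            for g in gs.genes:
                seen.setdefault(g, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]


def build_marker_sets(
    records: pd.DataFrame,
    alpha: float = 0.05,
    fc_min: float = 1.5,
    top_n: int = 200,
    descriptions: dict[str, str] | None = None,
) -> MarkerGeneSetCollection:
    """Filter marker test records and assemble per-type gene sets.

    Keeps genes with ``adjusted_p < alpha`` and ``fold_change >= fc_min``,
    orders by decreasing fold change (ties by smaller adjusted p, then
    symbol) and truncates to ``top_n``; if fewer pass, all passers are
    kept.  Empty sets are retained with a warning.
    """
    descriptions = descriptions or {}
    coll = MarkerGeneSetCollection()
    for ct, grp in records.groupby("cell_type", sort=True):
        passing = grp[(grp["adjusted_p"] < alpha) & (grp["fold_change"] >= fc_min)]
        ordered = passing.sort_values(
            ["fold_change", "adjusted_p", "gene"], ascending=[False, True, True]
        )
        genes = ordered["gene"].head(top_n).tolist()
        if not genes:
            logger.warning("cell type %r: no genes passed the marker filters", ct)
        coll.sets[str(ct)] = GeneSet(
            name=str(ct),
            description=descriptions.get(str(ct), f"{ct} markers"),
            genes=genes,
        )
    return coll


def write_gmt(collection: MarkerGeneSetCollection, path: str | Path) -> None:
    """Serialize as GMT: one set per line, name TAB description TAB genes."""
    names = collection.names
    if len(set(names)) != len(names):
        raise ValueError("set names must be unique for GMT output")
    with open(path, "w") as fh:
        for gs in collection.sets.values():
            # a trailing empty field keeps >=3 columns for empty sets
            genes = gs.genes if gs.genes else [""]
            fh.write("\t".join([gs.name, gs.description, *genes]) + "\n")


def read_gmt(path: str | Path) -> MarkerGeneSetCollection:
    coll = MarkerGeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: fewer than 3 fields")
            name, desc = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            coll.sets[name] = GeneSet(name=name, description=desc, genes=genes)
    return coll


def marker_pipeline(
    atlas: ReferenceCellAtlas,
    alpha: float = 0.05,
    fc_min: float = 1.5,
    top_n: int = 200,
    normalization: str = "library-median",
) -> tuple[MarkerGeneSetCollection, pd.DataFrame]:
    """Normalize, test, and assemble marker sets in one call."""
    norm = normalize_reference_for_markers(atlas, method=normalization)
    records = rank_markers(norm, atlas.obs["cell_type"])
    return build_marker_sets(records, alpha=alpha, fc_min=fc_min, top_n=top_n), records
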
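"""Cell-type association scoring of bulk RNA-seq samples.

The method is a linear deconvolution statistic, not a proportion
estimator.  From the single-cell reference, the mean expression of every
gene in every cell type is computed and centered per gene by subtracting
the unweighted mean over cell types, giving a *relative cell type
association score* per (gene, type).  Bulk samples are normalized to
counts per million and each cell type is scored as

    score(sample, type) = sum_g CPM(g, sample) * relative_score(g, type)

over the genes shared between bulk and signature.  Group differences per
cell type are assessed with a two-tailed two-sample t test (Welch by
default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .exceptions import (
    DegenerateSignatureError,
    IncompatibilityError,
    InsufficientReplicationError,
    NormalizationError,
)
from .reference_prep import ReferenceCellAtlas

logger = logging.getLogger(__name__)

EXPRESSION_BASES = ("log1p-cpm", "cpm", "raw")


@dataclass
class SignatureMatrix:
    """Centered per-cell-type mean expression, genes x cell types.

    Every gene row sums to zero across cell types, so positive entries
    mark types in which the gene is enriched relative to the others.
    """

    relative_score: pd.DataFrame
    expression_basis: str = "log1p-cpm"

    @property
    def cell_types(self) -> list[str]:
        return list(self.relative_score.columns)

    @property
    def genes(self) -> pd.Index:
        return self.relative_score.index


@dataclass
class CPMMatrix:
    """Counts-per-million bulk expression (genes x samples) with optional
    per-sample group labels."""

    cpm: pd.DataFrame
    group: pd.Series | None = None

    @property
    def sample_ids(self) -> pd.Index:
        return self.cpm.columns


@dataclass
class CellTypeScoreResult:
    """Per-sample, per-cell-type association scores.

    ``score`` holds the gene-summed scores (samples x cell types);
    ``score_per_gene`` divides by the size of the gene overlap so runs
    with different overlaps remain comparable.  ``group_stats`` is filled
    in by :func:`compare_groups`.
    """

    score: pd.DataFrame
    score_per_gene: pd.DataFrame
    group: pd.Series | None = None
    n_overlap_genes: int = 0
    group_stats: pd.DataFrame | None = field(default=None)


def _per_cell_expression(atlas: ReferenceCellAtlas, basis: str) -> pd.DataFrame:
    if basis not in EXPRESSION_BASES:
        raise ValueError(f"unknown expression basis {basis!r}; use one of {EXPRESSION_BASES}")
    counts = atlas.counts.astype(float)
    if basis == "raw":
        return counts
    libs = counts.sum(axis=0)
    zero = libs[libs <= 0]
    if len(zero):
        raise NormalizationError(f"cells with zero library size: {list(zero.index)[:5]}")
    cpm = counts / libs * 1e6
    if basis == "cpm":
        return cpm
    return np.log1p(cpm)


def compute_signature(
    atlas: ReferenceCellAtlas,
    basis: str = "log1p-cpm",
    per_sample_means: bool = False,
) -> SignatureMatrix:
    """Centered per-type mean expression of the reference.

    Per-type means are computed over all cells of a type; with
    ``per_sample_means`` they are first computed per (type, sample) and
    then averaged over samples with equal weight, which removes dominance
    by deeply sampled donors.  Each gene row is then centered by the
    unweighted mean across cell types.
    """
    types = atlas.cell_types
    if len(types) < 2:
        raise DegenerateSignatureError("need at least 2 cell types for a centered signature")
    expr = _per_cell_expression(atlas, basis)
    if per_sample_means:
        cols = {}
        for t in types:
            cells = atlas.obs.index[atlas.obs["cell_type"] == t]
            sub = expr[cells]
            by_sample = sub.T.groupby(atlas.obs.loc[cells, "sample_id"], observed=True).mean()
            cols[t] = by_sample.mean(axis=0)
        means = pd.DataFrame(cols)
    else:
        means = expr.T.groupby(atlas.obs["cell_type"], observed=True).mean().T
        means = means[types]
    centered = means.sub(means.mean(axis=1), axis=0)
    return SignatureMatrix(relative_score=centered, expression_basis=basis)


def cpm_normalize(
    bulk_counts: pd.DataFrame, group: pd.Series | None = None
) -> CPMMatrix:
    """Scale every bulk sample column to one million total counts.

    Computed on the full library, before any gene intersection with the
    signature.
    """
    counts = bulk_counts.astype(float)
    if (counts.to_numpy() < 0).any():
        raise NormalizationError("bulk counts contain negative values")
    libs = counts.sum(axis=0)
    zero = libs[libs <= 0]
    if len(zero):
        raise NormalizationError(f"samples with zero library size: {list(zero.index)}")
    cpm = counts / libs * 1e6
    if group is not None:
        group = group.reindex(cpm.columns)
        if group.isna().any():
            raise NormalizationError("group labels missing for some samples")
    return CPMMatrix(cpm=cpm, group=group)


def score_samples(cpm: CPMMatrix, sig: SignatureMatrix) -> CellTypeScoreResult:
    """Weight bulk CPM by the centered signature and sum over shared genes."""
    shared = cpm.cpm.index.intersection(sig.genes)
    if len(shared) == 0:
        raise IncompatibilityError("bulk data and signature share no genes")
    logger.info(
        "scoring %d samples on %d/%d signature genes",
        cpm.cpm.shape[1], len(shared), len(sig.genes),
    )
    score = cpm.cpm.loc[shared].T @ sig.relative_score.loc[shared]
    return CellTypeScoreResult(
        score=score,
        score_per_gene=score / len(shared),
        group=cpm.group,
        n_overlap_genes=len(shared),
    )


def _two_sample_t(
    a: np.ndarray, b: np.ndarray, equal_var: bool
) -> tuple[float, float]:
    """Two-tailed two-sample t; degenerate zero-variance cases resolved
    as t=0, p=1 when the means agree and p=0 otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = scipy.stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def compare_groups(
    result: CellTypeScoreResult,
    group: pd.Series | None = None,
    equal_var: bool = False,
    adjust: str | None = None,
) -> CellTypeScoreResult:
    """Attach per-cell-type two-group comparison statistics.

    Welch's t test by default (``equal_var=True`` for the Student
    variant).  ``adjust='bh'`` additionally reports BH-adjusted p values
    across cell types; by default each type is tested marginally.
    """
    group = group if group is not None else result.group
    if group is None:
        raise InsufficientReplicationError("no group labels available")
    group = group.reindex(result.score.index)
    levels = [g for g in pd.unique(group) if pd.notna(g)]
    if len(levels) != 2:
        raise InsufficientReplicationError(
            f"exactly 2 groups required, found {len(levels)}"
        )
    g1, g2 = levels
    idx1 = group.index[group == g1]
    idx2 = group.index[group == g2]
    if len(idx1) < 2 or len(idx2) < 2:
        raise InsufficientReplicationError("each group needs >= 2 samples")

    rows = []
    for ct in result.score.columns:
        a = result.score.loc[idx1, ct].to_numpy()
        b = result.score.loc[idx2, ct].to_numpy()
        t, p = _two_sample_t(a, b, equal_var=equal_var)
        rows.append({
            "cell_type": ct,
            f"mean_{g1}": a.mean(), f"sd_{g1}": a.std(ddof=1), f"n_{g1}": len(a),
            f"mean_{g2}": b.mean(), f"sd_{g2}": b.std(ddof=1), f"n_{g2}": len(b),
            "t": t, "p": p,
        })
    stats = pd.DataFrame(rows).set_index("cell_type")
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests
        stats["adjusted_p"] = multipletests(stats["p"], method="fdr_bh")[1]
    result.group_stats = stats
    result.group = group
    return result
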
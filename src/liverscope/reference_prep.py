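"""Loading and cleaning of a labeled single-cell reference.

The reference is a genes x cells count matrix with a cell-type and a
sample-of-origin label per cell.  Cleaning consists of five steps, applied
in this order by :func:`preprocess_reference`:

1. drop (cell type, sample) combinations observed in fewer than
   ``min_cells`` cells, so per-sample mean expression is estimable;
2. optionally rename genes to orthologs in a target species, resolving
   many-to-one relations by keeping the most highly expressed source gene;
3. drop genes detected (count > 0) in fewer than ``min_cells_detected``
   cells;
4. deduplicate gene symbols, keeping the copy with the highest mean count;
5. drop mitochondrial / ribosomal transcripts (prefix match) and an
   explicit cell-cycle gene list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .exceptions import (
    ConfigurationError,
    EmptyAtlasError,
    FormatError,
    SchemaError,
)

logger = logging.getLogger(__name__)

OBS_COLUMNS = ("cell_type", "sample_id")

#: Default mitochondrial / ribosomal symbol prefixes (case-sensitive).
MOUSE_MITO_PREFIXES = ("mt-",)
MOUSE_RIBO_PREFIXES = ("Rps", "Rpl")
HUMAN_MITO_PREFIXES = ("MT-",)
HUMAN_RIBO_PREFIXES = ("RPS", "RPL")


@dataclass(frozen=True)
class GeneExclusionLists:
    """Symbol prefixes / explicit lists of genes to drop from a reference."""

    mito_patterns: tuple[str, ...] = MOUSE_MITO_PREFIXES
    ribo_patterns: tuple[str, ...] = MOUSE_RIBO_PREFIXES
    cell_cycle_symbols: tuple[str, ...] = ()

    @classmethod
    def human(cls, cell_cycle_symbols: tuple[str, ...] = ()) -> "GeneExclusionLists":
        return cls(HUMAN_MITO_PREFIXES, HUMAN_RIBO_PREFIXES, cell_cycle_symbols)


@dataclass
class ReferenceCellAtlas:
    """Labeled single-cell count matrix.

    Attributes
    ----------
    counts
        Nonnegative integer matrix, genes as rows, cells as columns.
    obs
        One row per cell (index aligned with ``counts`` columns) with at
        least ``cell_type`` and ``sample_id`` columns.
    provenance
        Optional per-gene record of the ortholog source symbol, indexed by
        the current (target-namespace) gene symbol positions.
    """

    counts: pd.DataFrame
    obs: pd.DataFrame
    provenance: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        for col in OBS_COLUMNS:
            if col not in self.obs.columns:
                raise SchemaError(f"label table lacks required column {col!r}")
        if self.counts.shape[1] != len(self.obs):
            raise FormatError(
                f"count matrix has {self.counts.shape[1]} cells but the label "
                f"table has {len(self.obs)} rows"
            )
        if not self.counts.columns.equals(self.obs.index):
            raise SchemaError("cell identifiers in counts and labels do not align")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("count matrix contains negative values")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_symbols(self) -> pd.Index:
        return self.counts.index

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.obs["cell_type"].unique())

    def _with_counts(self, counts: pd.DataFrame) -> "ReferenceCellAtlas":
        prov = self.provenance
        if prov is not None:
            prov = prov.reindex(counts.index.unique()).dropna()
        return ReferenceCellAtlas(counts=counts, obs=self.obs, provenance=prov)

    def subset_cells(self, keep: pd.Index) -> "ReferenceCellAtlas":
        return ReferenceCellAtlas(
            counts=self.counts.loc[:, keep],
            obs=self.obs.loc[keep],
            provenance=self.provenance,
        )


def load_reference(
    counts_path: str | Path,
    labels_path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> ReferenceCellAtlas:
    """Read a genes x cells count matrix plus a cell label table.

    ``counts_path`` may be a TSV (gene symbols in the first column, header
    row of cell identifiers) or a Matrix Market ``.mtx`` triplet file with
    sidecar ``genes_path`` / ``cells_path`` one-symbol-per-line files
    (defaults: the matrix path with ``.genes.txt`` / ``.cells.txt``
    suffixes).  The label table is a TSV with columns ``cell_id``,
    ``cell_type`` and ``sample_id``.
    """
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        genes_path = Path(genes_path) if genes_path else counts_path.with_suffix(".genes.txt")
        cells_path = Path(cells_path) if cells_path else counts_path.with_suffix(".cells.txt")
        try:
            mat = scipy.io.mmread(counts_path)
        except ValueError as exc:
            raise FormatError(f"cannot parse MTX file {counts_path}: {exc}") from exc
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = [line.strip() for line in Path(genes_path).read_text().splitlines() if line.strip()]
        cells = [line.strip() for line in Path(cells_path).read_text().splitlines() if line.strip()]
        if mat.shape != (len(genes), len(cells)):
            raise FormatError(
                f"MTX matrix is {mat.shape} but sidecars list "
                f"{len(genes)} genes and {len(cells)} cells"
            )
        counts = pd.DataFrame(np.asarray(mat), index=pd.Index(genes, name="gene"), columns=cells)
    else:
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        counts.index.name = "gene"

    labels = pd.read_csv(labels_path, sep="\t", dtype=str)
    if "cell_id" not in labels.columns:
        raise SchemaError("label table lacks required column 'cell_id'")
    labels = labels.set_index("cell_id")
    if len(labels) != counts.shape[1]:
        raise SchemaError(
            f"label table has {len(labels)} rows for {counts.shape[1]} cells"
        )
    missing = counts.columns.difference(labels.index)
    if len(missing):
        raise SchemaError(f"cells missing from label table: {list(missing)[:5]}")
    labels = labels.loc[counts.columns]

    if not np.issubdtype(counts.to_numpy().dtype, np.number):
        raise FormatError("count matrix contains non-numeric entries")
    return ReferenceCellAtlas(counts=counts, obs=labels)


def load_ortholog_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV of (source_symbol, target_symbol, homology_class) rows."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    return validate_ortholog_table(table)


def validate_ortholog_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"source_symbol", "target_symbol", "homology_class"}
    missing = required - set(table.columns)
    if missing:
        raise SchemaError(f"ortholog table lacks columns {sorted(missing)}")
    if table.duplicated(["source_symbol", "target_symbol"]).any():
        raise SchemaError("ortholog table has duplicate (source, target) pairs")
    return table


def filter_celltype_sample_combos(
    atlas: ReferenceCellAtlas, min_cells: int = 10
) -> ReferenceCellAtlas:
    """Remove cells of every (cell_type, sample_id) combination with fewer
    than ``min_cells`` cells, so per-sample type means are estimable."""
    if min_cells < 1:
        raise ConfigurationError("min_cells must be >= 1")
    sizes = atlas.obs.groupby(["cell_type", "sample_id"], observed=True).size()
    keep_combos = sizes[sizes >= min_cells].index
    combo = pd.MultiIndex.from_frame(atlas.obs[["cell_type", "sample_id"]])
    keep = atlas.obs.index[combo.isin(keep_combos)]
    if len(keep) == 0:
        raise EmptyAtlasError("no (cell type, sample) combination has enough cells")
    dropped_types = set(atlas.obs["cell_type"]) - set(atlas.obs.loc[keep, "cell_type"])
    if dropped_types:
        logger.info("cell types dropped entirely by combo filter: %s", sorted(dropped_types))
    logger.info(
        "combo filter (min %d cells): kept %d/%d cells", min_cells, len(keep), atlas.n_cells
    )
    return atlas.subset_cells(keep)


def map_orthologs(
    atlas: ReferenceCellAtlas,
    orth: pd.DataFrame,
    expand_one2many: bool = False,
) -> ReferenceCellAtlas:
    """Rename gene rows from source to target symbols.

    Only ``one2one`` and ``many2one`` relations are used by default; with
    ``expand_one2many`` the ``one2many`` rows are also used, duplicating
    the source row under each target.  When several source genes map to one
    target, the source with the highest total count across all cells is
    kept; ties break toward the lexicographically smaller source symbol.
    Unmapped genes are dropped.
    """
    orth = validate_ortholog_table(orth)
    if len(orth) == 0:
        raise ConfigurationError("ortholog table is empty")
    classes = {"one2one", "many2one"}
    if expand_one2many:
        classes |= {"one2many", "many2many"}
    usable = orth[orth["homology_class"].isin(classes)]
    usable = usable[usable["source_symbol"].isin(atlas.gene_symbols)]

    totals = atlas.counts.sum(axis=1)

    chosen: list[tuple[str, str]] = []  # (source, target)
    for target, grp in usable.groupby("target_symbol", sort=True):
        cands = sorted(grp["source_symbol"].unique())
        # highest total expression wins; ties -> lexicographically smaller
        best_total = max(totals[s] for s in cands)
        best = min(s for s in cands if totals[s] == best_total)
        chosen.append((best, target))

    if not chosen:
        raise EmptyAtlasError("no gene could be mapped to a target ortholog")

    n_unmapped = atlas.n_genes - len({s for s, _ in chosen})
    logger.info("ortholog mapping: %d gene rows unmapped and dropped", n_unmapped)

    # keep original row order of the source genes; expansion targets sort after
    order = {g: i for i, g in enumerate(atlas.gene_symbols)}
    chosen.sort(key=lambda st: (order[st[0]], st[1]))
    sources = [s for s, _ in chosen]
    targets = [t for _, t in chosen]
    counts = atlas.counts.loc[sources]
    counts.index = pd.Index(targets, name="gene")
    provenance = pd.Series(sources, index=counts.index, name="source_symbol")
    return ReferenceCellAtlas(counts=counts, obs=atlas.obs, provenance=provenance)


def filter_low_detection_genes(
    atlas: ReferenceCellAtlas, min_cells_detected: int = 20
) -> ReferenceCellAtlas:
    """Drop genes with a nonzero count in fewer than ``min_cells_detected``
    cells."""
    if min_cells_detected < 0:
        raise ConfigurationError("min_cells_detected must be >= 0")
    detected = (atlas.counts > 0).sum(axis=1)
    keep = detected >= min_cells_detected
    if not keep.any():
        raise EmptyAtlasError("detection filter removed every gene")
    logger.info(
        "detection filter (>=%d cells): kept %d/%d genes",
        min_cells_detected, int(keep.sum()), atlas.n_genes,
    )
    return atlas._with_counts(atlas.counts.loc[keep.to_numpy()])


def dedup_gene_symbols(atlas: ReferenceCellAtlas) -> ReferenceCellAtlas:
    """Among rows sharing a symbol keep the one with the highest mean count
    (first occurrence on ties)."""
    means = atlas.counts.mean(axis=1).to_numpy()
    symbols = atlas.counts.index
    best_pos: dict[str, int] = {}
    for pos, sym in enumerate(symbols):
        prev = best_pos.get(sym)
        if prev is None or means[pos] > means[prev]:
            best_pos[sym] = pos
    keep = sorted(best_pos.values())
    if len(keep) < atlas.n_genes:
        logger.info("dedup: removed %d duplicate gene rows", atlas.n_genes - len(keep))
    return atlas._with_counts(atlas.counts.iloc[keep])


def exclude_gene_categories(
    atlas: ReferenceCellAtlas, lists: GeneExclusionLists
) -> ReferenceCellAtlas:
    """Drop mitochondrial / ribosomal (prefix match, case-sensitive) and
    cell-cycle (exact symbol) genes."""
    symbols = atlas.gene_symbols
    mito = symbols.str.startswith(lists.mito_patterns) if lists.mito_patterns else pd.Index([False] * len(symbols))
    ribo = symbols.str.startswith(lists.ribo_patterns) if lists.ribo_patterns else pd.Index([False] * len(symbols))
    cc = symbols.isin(lists.cell_cycle_symbols)
    mito = np.asarray(mito, dtype=bool)
    ribo = np.asarray(ribo, dtype=bool)
    cc = np.asarray(cc, dtype=bool)
    logger.info(
        "category exclusion: %d mito, %d ribo, %d cell-cycle genes removed",
        int(mito.sum()), int((ribo & ~mito).sum()), int((cc & ~mito & ~ribo).sum()),
    )
    keep = ~(mito | ribo | cc)
    if not keep.any():
        raise EmptyAtlasError("category exclusion removed every gene")
    return atlas._with_counts(atlas.counts.loc[keep])


def preprocess_reference(
    atlas: ReferenceCellAtlas,
    orthologs: pd.DataFrame | None = None,
    exclusion: GeneExclusionLists | None = None,
    min_cells: int = 10,
    min_cells_detected: int = 20,
    expand_one2many: bool = False,
) -> ReferenceCellAtlas:
    """Full cleaning chain: combos -> orthologs -> detection -> dedup ->
    category exclusion."""
    atlas = filter_celltype_sample_combos(atlas, min_cells=min_cells)
    if orthologs is not None:
        atlas = map_orthologs(atlas, orthologs, expand_one2many=expand_one2many)
    atlas = filter_low_detection_genes(atlas, min_cells_detected=min_cells_detected)
    atlas = dedup_gene_symbols(atlas)
    if exclusion is not None:
        atlas = exclude_gene_categories(atlas, exclusion)
    return atlas
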
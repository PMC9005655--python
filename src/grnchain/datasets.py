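"""Expression data containers, loaders and feature selection.

The central container is :class:`ExpressionDataset`: an imputed genes x cells
expression matrix together with an ordered list of cell phenotypes (states),
a driver/target partition of the genes, and optional per-cell cluster labels.
Internally the math works on cells x genes blocks (one per phenotype); on
disk the conventional genes-as-rows orientation is used.

Expression is assumed to be imputed (no missing values) and already
normalized by the user; no library-size normalization or log transform is
applied here.  :func:`log1p` is provided as an opt-in convenience.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "TrainTestSplit",
    "load_expression",
    "write_expression",
    "mad",
    "select_features_by_mad",
    "split_train_test",
    "log1p",
]


@dataclass
class ExpressionDataset:
    """Imputed expression matrix with phenotype ordering and gene partition.

    Parameters
    ----------
    matrix
        Dense ``(n_genes, n_cells)`` float array, no missing entries.
    gene_ids, cell_ids
        Ordered identifiers for rows and columns of ``matrix``.
    phenotype_of_cell
        Maps every cell id to a phenotype label.
    phenotype_order
        The user-supplied linear ordering of the K >= 2 phenotype labels;
        the similarity penalty of the joint fit couples consecutive labels.
    cluster_of_cell
        Optional cell -> cluster label map used by the dissimilarity table.
    driver_ids, target_ids
        Disjoint subsets of ``gene_ids``; drivers (TFs) predict targets.
    """

    matrix: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    phenotype_of_cell: dict[str, str]
    phenotype_order: list[str]
    driver_ids: list[str]
    target_ids: list[str]
    cluster_of_cell: dict[str, str] | None = None

    _gene_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if np.isnan(self.matrix).any():
            raise ValueError("expression matrix contains missing values; input must be imputed")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if len(self.phenotype_order) != len(set(self.phenotype_order)):
            raise ValueError("phenotype_order contains duplicates")
        if len(self.phenotype_order) < 2:
            raise ValueError("need at least two phenotypes (K >= 2)")
        known = set(self.phenotype_order)
        for cid in self.cell_ids:
            ph = self.phenotype_of_cell.get(cid)
            if ph is None:
                raise ValueError(f"cell {cid!r} has no phenotype label")
            if ph not in known:
                raise ValueError(f"cell {cid!r} has unknown phenotype {ph!r}")
        gene_set = set(self.gene_ids)
        drivers, targets = set(self.driver_ids), set(self.target_ids)
        if drivers & targets:
            raise ValueError("driver and target gene sets overlap")
        if not drivers <= gene_set or not targets <= gene_set:
            raise ValueError("driver/target ids must be a subset of gene_ids")
        if not self.driver_ids:
            raise ValueError("empty driver set")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    # -- basic dimensions (paper-style shorthand) --------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_drivers(self) -> int:
        return len(self.driver_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    @property
    def n_phenotypes(self) -> int:
        return len(self.phenotype_order)

    def cells_of_phenotype(self, label: str) -> list[str]:
        if label not in self.phenotype_order:
            raise KeyError(label)
        return [c for c in self.cell_ids if self.phenotype_of_cell[c] == label]

    def cell_counts(self) -> dict[str, int]:
        """Cells per phenotype (the s_k of the joint objective)."""
        return {ph: len(self.cells_of_phenotype(ph)) for ph in self.phenotype_order}

    # -- matrix views ------------------------------------------------------
    def _rows(self, gene_ids: list[str]) -> np.ndarray:
        idx = [self._gene_index[g] for g in gene_ids]
        return self.matrix[idx, :]

    def driver_block(self, phenotype: str, cell_ids: list[str] | None = None) -> np.ndarray:
        """Cells x drivers expression for one phenotype (the X^k block)."""
        return self._block(self.driver_ids, phenotype, cell_ids)

    def target_block(self, phenotype: str, cell_ids: list[str] | None = None) -> np.ndarray:
        """Cells x targets expression for one phenotype (the Y^k block)."""
        return self._block(self.target_ids, phenotype, cell_ids)

    def _block(self, genes: list[str], phenotype: str, cell_ids: list[str] | None) -> np.ndarray:
        if cell_ids is None:
            cell_ids = self.cells_of_phenotype(phenotype)
        cidx = {c: j for j, c in enumerate(self.cell_ids)}
        cols = [cidx[c] for c in cell_ids]
        return self._rows(genes)[:, cols].T.copy()

    def subset_genes(self, driver_ids: list[str], target_ids: list[str]) -> "ExpressionDataset":
        keep = list(driver_ids) + list(target_ids)
        return ExpressionDataset(
            matrix=self._rows(keep),
            gene_ids=keep,
            cell_ids=list(self.cell_ids),
            phenotype_of_cell=dict(self.phenotype_of_cell),
            phenotype_order=list(self.phenotype_order),
            driver_ids=list(driver_ids),
            target_ids=list(target_ids),
            cluster_of_cell=None if self.cluster_of_cell is None else dict(self.cluster_of_cell),
        )

    def subset_cells(self, cell_ids: list[str]) -> "ExpressionDataset":
        cidx = {c: j for j, c in enumerate(self.cell_ids)}
        cols = [cidx[c] for c in cell_ids]
        return ExpressionDataset(
            matrix=self.matrix[:, cols],
            gene_ids=list(self.gene_ids),
            cell_ids=list(cell_ids),
            phenotype_of_cell={c: self.phenotype_of_cell[c] for c in cell_ids},
            phenotype_order=list(self.phenotype_order),
            driver_ids=list(self.driver_ids),
            target_ids=list(self.target_ids),
            cluster_of_cell=None
            if self.cluster_of_cell is None
            else {c: self.cluster_of_cell[c] for c in cell_ids},
        )


@dataclass
class TrainTestSplit:
    """Stratified train/test partition of cells, per phenotype."""

    train_cell_ids: dict[str, list[str]]
    test_cell_ids: dict[str, list[str]]
    ratio: float
    seed: int

    def all_train(self) -> list[str]:
        return [c for ph in self.train_cell_ids for c in self.train_cell_ids[ph]]

    def all_test(self) -> list[str]:
        return [c for ph in self.test_cell_ids for c in self.test_cell_ids[ph]]


# ---------------------------------------------------------------------------
# loading / writing


def _read_driver_list(path) -> list[str]:
    drivers: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                drivers.append(line)
    return drivers


def _read_matrix(matrix_path, cells_as_rows: bool) -> pd.DataFrame:
    """Read a dense TSV/CSV (genes x cells) or an MTX triplet into a genes x cells frame."""
    p = str(matrix_path)
    if p.endswith(".mtx"):
        import os

        base = os.path.dirname(p)
        m = mmread(p).toarray()
        genes = pd.read_csv(os.path.join(base, "genes.tsv"), sep="\t", header=None)[0].tolist()
        cells = pd.read_csv(os.path.join(base, "barcodes.tsv"), sep="\t", header=None)[0].tolist()
        df = pd.DataFrame(m, index=genes, columns=cells)
    else:
        sep = "," if p.endswith(".csv") else "\t"
        df = pd.read_csv(p, sep=sep, index_col=0)
    if cells_as_rows:
        df = df.T
    return df


def load_expression(
    matrix_path,
    metadata_path,
    driver_list_path,
    phenotype_order: list[str],
    cells_as_rows: bool = False,
) -> ExpressionDataset:
    """Load and validate an expression matrix, cell metadata and a driver list.

    The metadata table must have columns ``cell_id`` and ``phenotype`` and may
    have a ``cluster`` column.  Genes listed in the driver file become the
    driver set; every other gene is a target.  Cells absent from the metadata
    are dropped with a warning; a phenotype label outside ``phenotype_order``
    is a hard error.
    """
    df = _read_matrix(matrix_path, cells_as_rows)
    meta = pd.read_csv(metadata_path, sep=None, engine="python")
    if "cell_id" not in meta.columns or "phenotype" not in meta.columns:
        raise ValueError("metadata must have columns 'cell_id' and 'phenotype'")
    meta = meta.set_index("cell_id")

    cells = [c for c in df.columns if c in meta.index]
    dropped = len(df.columns) - len(cells)
    if dropped:
        logger.warning("dropping %d cells absent from metadata", dropped)
        warnings.warn(f"dropping {dropped} cells absent from metadata", stacklevel=2)
    df = df[cells]

    phenotype_of_cell = {c: str(meta.loc[c, "phenotype"]) for c in cells}
    unknown = set(phenotype_of_cell.values()) - set(phenotype_order)
    if unknown:
        raise ValueError(f"phenotype labels {sorted(unknown)} not in phenotype_order")

    cluster_of_cell = None
    if "cluster" in meta.columns:
        cluster_of_cell = {c: str(meta.loc[c, "cluster"]) for c in cells}

    drivers = _read_driver_list(driver_list_path)
    gene_ids = list(df.index)
    gene_set = set(gene_ids)
    driver_ids = [g for g in gene_ids if g in set(drivers) & gene_set]
    if not driver_ids:
        raise ValueError("no driver genes found in the expression matrix")
    target_ids = [g for g in gene_ids if g not in set(driver_ids)]

    return ExpressionDataset(
        matrix=df.to_numpy(dtype=float),
        gene_ids=gene_ids,
        cell_ids=cells,
        phenotype_of_cell=phenotype_of_cell,
        phenotype_order=list(phenotype_order),
        driver_ids=driver_ids,
        target_ids=target_ids,
        cluster_of_cell=cluster_of_cell,
    )


def write_expression(ds: ExpressionDataset, out_dir, sparse: bool = False) -> None:
    """Write a dataset in the formats :func:`load_expression` reads back.

    Emits ``matrix.tsv`` (or ``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``),
    ``metadata.tsv`` and ``drivers.txt`` under ``out_dir``.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    if sparse:
        mmwrite(os.path.join(out_dir, "matrix.mtx"), coo_matrix(ds.matrix))
        pd.Series(ds.gene_ids).to_csv(
            os.path.join(out_dir, "genes.tsv"), sep="\t", header=False, index=False
        )
        pd.Series(ds.cell_ids).to_csv(
            os.path.join(out_dir, "barcodes.tsv"), sep="\t", header=False, index=False
        )
    else:
        df = pd.DataFrame(ds.matrix, index=ds.gene_ids, columns=ds.cell_ids)
        df.index.name = "gene_id"
        df.to_csv(os.path.join(out_dir, "matrix.tsv"), sep="\t")
    meta = pd.DataFrame(
        {
            "cell_id": ds.cell_ids,
            "phenotype": [ds.phenotype_of_cell[c] for c in ds.cell_ids],
        }
    )
    if ds.cluster_of_cell is not None:
        meta["cluster"] = [ds.cluster_of_cell[c] for c in ds.cell_ids]
    meta.to_csv(os.path.join(out_dir, "metadata.tsv"), sep="\t", index=False)
    with open(os.path.join(out_dir, "drivers.txt"), "w") as fh:
        fh.write("\n".join(ds.driver_ids) + "\n")


# ---------------------------------------------------------------------------
# feature selection


def mad(values, center: str = "mean") -> float:
    """Median absolute deviation of a vector.

    By default deviations are taken from the MEAN of the vector
    (``median(|v - mean(v)|)``), which is the variability measure used for
    feature selection here; note this differs from the conventional
    median-centered MAD, available via ``center="median"``.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("mad of an empty vector is undefined")
    if center == "mean":
        c = v.mean()
    elif center == "median":
        c = np.median(v)
    else:
        raise ValueError("center must be 'mean' or 'median'")
    return float(np.median(np.abs(v - c)))


def select_features_by_mad(
    ds: ExpressionDataset, n_drivers: int, n_targets: int, center: str = "mean"
) -> ExpressionDataset:
    """Keep the ``n_drivers`` most variable drivers and ``n_targets`` most
    variable targets, variability measured by :func:`mad` over all cells.

    Relative gene order is preserved; ties are broken by original gene order
    (stable sort), so repeated runs are reproducible.
    """
    if n_drivers > ds.n_drivers or n_targets > ds.n_targets:
        raise ValueError("requested more genes than available")

    def top(ids: list[str], n: int) -> list[str]:
        scores = np.array([mad(ds._rows([g])[0], center=center) for g in ids])
        # stable sort on -score keeps original order among ties
        order = np.argsort(-scores, kind="stable")[:n]
        keep = set(order.tolist())
        return [g for i, g in enumerate(ids) if i in keep]

    return ds.subset_genes(top(ds.driver_ids, n_drivers), top(ds.target_ids, n_targets))


def split_train_test(ds: ExpressionDataset, ratio: float = 0.8, seed: int = 0) -> TrainTestSplit:
    """Stratified train/test split of cells within each phenotype.

    ``ratio`` is the training fraction (0.8 gives the conventional 80/20
    split used for goodness-of-fit assessment).  Deterministic given ``seed``.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: dict[str, list[str]] = {}
    test: dict[str, list[str]] = {}
    for ph in ds.phenotype_order:
        cells = ds.cells_of_phenotype(ph)
        if len(cells) < 2:
            raise ValueError(f"phenotype {ph!r} has fewer than 2 cells; cannot split")
        perm = rng.permutation(len(cells))
        n_train = int(round(ratio * len(cells)))
        n_train = min(max(n_train, 1), len(cells) - 1)
        train[ph] = sorted(cells[i] for i in perm[:n_train])
        test[ph] = sorted(cells[i] for i in perm[n_train:])
    return TrainTestSplit(train_cell_ids=train, test_cell_ids=test, ratio=ratio, seed=seed)


def log1p(ds: ExpressionDataset) -> ExpressionDataset:
    """Return a copy of the dataset with log1p-transformed expression (opt-in)."""
    out = ds.subset_cells(list(ds.cell_ids))
    out.matrix = np.log1p(out.matrix)
    return out
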
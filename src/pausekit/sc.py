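"""Single-cell UMI matrix QC, normalization, anchor-gene covariance shifts,
transgene census, and pseudobulk/bulk concordance.

The covariance-shift analysis asks, for a chosen anchor gene (e.g. *Ar*),
which genes change their co-expression with the anchor between two
conditions: for every gene g the sample covariance between g and the anchor
is computed across cells in each condition and the difference
cov(condition 1) − cov(condition 2) is thresholded. Covariances are taken on
total-count-normalized, un-logged expression by default, with the scale
recorded in the output metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from scipy import stats

__all__ = [
    "CellMatrix",
    "QCReport",
    "ConcordanceResult",
    "qc_filter_cells",
    "normalize_cells",
    "anchor_covariance_shift",
    "transgene_census",
    "pseudobulk_concordance",
]


def default_mito_mask(genes: Sequence[str]) -> np.ndarray:
    return np.array([g.lower().startswith("mt-") for g in genes], dtype=bool)


@dataclass
class CellMatrix:
    """Genes x cells UMI counts with per-cell population labels.

    ``counts`` is CSR, genes in rows. ``mito_gene_mask`` defaults to gene ids
    with a case-insensitive ``mt-`` prefix.
    """

    genes: list[str]
    cells: list[str]
    counts: sp.csr_matrix
    cell_labels: np.ndarray
    condition: str = ""
    mito_gene_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_labels = np.asarray(self.cell_labels, dtype=object)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if len(self.cell_labels) != len(self.cells):
            raise ValueError("cell_labels must cover all cells")
        if self.counts.nnz and (
            np.any(self.counts.data < 0)
            or np.any(self.counts.data != np.round(self.counts.data))
        ):
            raise ValueError("counts must be non-negative integers")
        if self.mito_gene_mask is None:
            self.mito_gene_mask = default_mito_mask(self.genes)
        self.mito_gene_mask = np.asarray(self.mito_gene_mask, dtype=bool)
        if len(self.mito_gene_mask) != len(self.genes):
            raise ValueError("mito_gene_mask must have one flag per gene")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.genes.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None

    # -- IO -----------------------------------------------------------------

    def to_mtx(self, outdir: str | Path) -> None:
        """MatrixMarket triplet plus genes.tsv / barcodes.tsv / labels.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(self.counts))
        (outdir / "genes.tsv").write_text("".join(f"{g}\n" for g in self.genes))
        (outdir / "barcodes.tsv").write_text("".join(f"{c}\n" for c in self.cells))
        with open(outdir / "labels.tsv", "w") as fh:
            fh.write("barcode\tpopulation\tcondition\n")
            for cell, label in zip(self.cells, self.cell_labels):
                fh.write(f"{cell}\t{label}\t{self.condition}\n")

    @classmethod
    def from_mtx(cls, indir: str | Path) -> "CellMatrix":
        indir = Path(indir)
        counts = sp.csr_matrix(scipy.io.mmread(str(indir / "matrix.mtx")))
        genes = (indir / "genes.tsv").read_text().splitlines()
        cells = (indir / "barcodes.tsv").read_text().splitlines()
        labels_path = indir / "labels.tsv"
        condition = ""
        if labels_path.exists():
            lab = pd.read_csv(labels_path, sep="\t", dtype=str)
            lab = lab.set_index("barcode").loc[cells]
            labels = lab["population"].to_numpy(dtype=object)
            if "condition" in lab.columns and len(lab):
                condition = str(lab["condition"].iloc[0])
        else:
            labels = np.array(["all"] * len(cells), dtype=object)
        return cls(
            genes=genes, cells=cells, counts=counts, cell_labels=labels,
            condition=condition,
        )

    @classmethod
    def from_dense_tsv(
        cls,
        path: str | Path,
        labels: Mapping[str, str] | None = None,
        condition: str = "",
    ) -> "CellMatrix":
        """Dense genes x cells TSV with a header of barcodes and gene ids in
        the first column."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        cells = [str(c) for c in df.columns]
        lab = np.array(
            [labels.get(c, "all") if labels else "all" for c in cells], dtype=object
        )
        return cls(
            genes=[str(g) for g in df.index],
            cells=cells,
            counts=sp.csr_matrix(df.to_numpy()),
            cell_labels=lab,
            condition=condition,
        )

    def subset_cells(self, keep: np.ndarray) -> "CellMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CellMatrix(
            genes=list(self.genes),
            cells=[self.cells[i] for i in keep],
            counts=self.counts[:, keep].tocsr(),
            cell_labels=self.cell_labels[keep],
            condition=self.condition,
            mito_gene_mask=self.mito_gene_mask.copy(),
        )


@dataclass
class QCReport:
    n_input: int
    n_kept: int
    removed: pd.DataFrame  # barcode, reason

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_kept


def qc_filter_cells(
    matrix: CellMatrix,
    min_genes: int = 200,
    max_mito_fraction: float = 0.80,
) -> tuple[CellMatrix, QCReport]:
    """Drop cells with *fewer than* ``min_genes`` expressed genes (UMI > 0) or
    *more than* ``max_mito_fraction`` of UMIs from mitochondrial genes;
    boundary cells are kept. Idempotent by construction.
    """
    expressed = (matrix.counts > 0).sum(axis=0).A1
    totals = np.asarray(matrix.counts.sum(axis=0)).ravel()
    mito = np.asarray(matrix.counts[matrix.mito_gene_mask].sum(axis=0)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_frac = np.where(totals > 0, mito / np.maximum(totals, 1), 1.0)
    low_genes = expressed < min_genes
    high_mito = mito_frac > max_mito_fraction
    keep = ~(low_genes | high_mito)
    if not keep.any():
        raise ValueError("QC removed every cell; check thresholds and inputs")
    reasons = []
    for i in np.flatnonzero(~keep):
        r = ";".join(
            tag for tag, bad in (("low_genes", low_genes[i]), ("high_mito", high_mito[i])) if bad
        )
        reasons.append((matrix.cells[i], r))
    report = QCReport(
        n_input=matrix.n_cells,
        n_kept=int(keep.sum()),
        removed=pd.DataFrame(reasons, columns=["barcode", "reason"]),
    )
    return matrix.subset_cells(keep), report


def normalize_cells(
    matrix: CellMatrix,
    scale_total: float = 10_000.0,
    log_transform: bool = False,
) -> np.ndarray:
    """Total-count normalization: count / cell_total * scale_total, optionally
    followed by log(1+x). Returns a dense genes x cells float array."""
    totals = np.asarray(matrix.counts.sum(axis=0)).ravel()
    if np.any(totals <= 0):
        bad = [matrix.cells[i] for i in np.flatnonzero(totals <= 0)][:5]
        raise ValueError(f"cells with zero total counts (run QC first): {bad}")
    dense = matrix.counts.toarray().astype(np.float64)
    dense *= scale_total / totals
    if log_transform:
        dense = np.log1p(dense)
    return dense


def _select_cells(matrix: CellMatrix, cell_mask) -> np.ndarray:
    if cell_mask is None:
        return np.arange(matrix.n_cells)
    if isinstance(cell_mask, str):
        cell_mask = [cell_mask]
    if isinstance(cell_mask, (list, tuple, set, frozenset)):
        wanted = set(cell_mask)
        return np.flatnonzero(np.isin(matrix.cell_labels, list(wanted)))
    mask = np.asarray(cell_mask)
    return np.flatnonzero(mask) if mask.dtype == bool else mask


def anchor_covariance_shift(
    matrix1: CellMatrix,
    matrix2: CellMatrix,
    anchor: str,
    threshold: float = 30.0,
    cell_mask=None,
    scale_total: float = 10_000.0,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Per-gene covariance with the anchor in each condition and the shift
    between them.

    Returns a table with columns gene_id, cov_condition1, cov_condition2,
    delta_cov and flagged (|delta_cov| > threshold); the expression scale is
    recorded in ``.attrs``. ``cell_mask`` restricts to a population label (or
    list of labels / boolean mask), e.g. the luminal subset.
    """
    shared = [g for g in matrix1.genes if g in set(matrix2.genes)]
    if anchor not in shared:
        raise KeyError(f"anchor gene {anchor!r} missing from one of the matrices")
    covs = {}
    for key, m in (("cov_condition1", matrix1), ("cov_condition2", matrix2)):
        idx = _select_cells(m, cell_mask)
        if len(idx) < 3:
            raise ValueError(
                f"{m.condition or key}: only {len(idx)} cells after masking; need >= 3"
            )
        sub = m.subset_cells(idx)
        expr = normalize_cells(sub, scale_total=scale_total, log_transform=log_transform)
        order = [sub.gene_index(g) for g in shared]
        expr = expr[order]
        a = expr[shared.index(anchor)]
        a_c = a - a.mean()
        x_c = expr - expr.mean(axis=1, keepdims=True)
        covs[key] = x_c @ a_c / (len(idx) - 1)
    out = pd.DataFrame(
        {
            "gene_id": shared,
            "cov_condition1": covs["cov_condition1"],
            "cov_condition2": covs["cov_condition2"],
        }
    )
    out["delta_cov"] = out["cov_condition1"] - out["cov_condition2"]
    out["flagged"] = out["delta_cov"].abs() > threshold
    out.attrs["expression_scale"] = (
        f"total-count normalized to {scale_total:g}"
        + (", log1p" if log_transform else ", un-logged")
    )
    out.attrs["threshold"] = threshold
    return out


def transgene_census(matrix: CellMatrix, transgene: str) -> pd.DataFrame:
    """Per-population count of transgene-positive cells (UMI > 0), with the
    percentage rounded to one decimal."""
    idx = matrix.gene_index(transgene)
    positive = (matrix.counts[idx] > 0).toarray().ravel()
    rows = []
    for pop in sorted(set(matrix.cell_labels)):
        in_pop = matrix.cell_labels == pop
        n_cells = int(in_pop.sum())
        n_pos = int(positive[in_pop].sum())
        rows.append((pop, n_cells, n_pos, round(100.0 * n_pos / n_cells, 1)))
    return pd.DataFrame(
        rows, columns=["population", "n_cells", "n_positive", "percent_positive"]
    )


@dataclass
class ConcordanceResult:
    pearson_r: float
    p_value: float
    n_both: int
    n_sc_only: int
    n_bulk_only: int
    field_note: str = field(
        default="Pearson r of log(sc UMI sum + 1) vs log(bulk count + 1) over "
        "genes expressed in both assays"
    )


def pseudobulk_concordance(
    matrix: CellMatrix, bulk_counts: Mapping[str, float] | pd.Series
) -> ConcordanceResult:
    """Concordance between summed single-cell UMIs and bulk read counts.

    A gene counts as expressed when its UMI sum (or bulk count) exceeds 0;
    the correlation is computed on log(x+1) over genes expressed in both.
    """
    bulk = pd.Series(bulk_counts, dtype=float)
    sc_sum = pd.Series(
        np.asarray(matrix.counts.sum(axis=1)).ravel(), index=matrix.genes, dtype=float
    )
    shared = sc_sum.index.intersection(bulk.index)
    if len(shared) < 10:
        raise ValueError(
            f"only {len(shared)} genes shared between single-cell and bulk; need >= 10"
        )
    sc_s, bk = sc_sum.loc[shared], bulk.loc[shared]
    both = (sc_s > 0) & (bk > 0)
    if both.sum() < 3:
        raise ValueError("fewer than 3 genes expressed in both assays")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r, p = stats.pearsonr(np.log(sc_s[both] + 1), np.log(bk[both] + 1))
    return ConcordanceResult(
        pearson_r=float(r),
        p_value=float(p),
        n_both=int(both.sum()),
        n_sc_only=int(((sc_s > 0) & (bk <= 0)).sum()),
        n_bulk_only=int(((sc_s <= 0) & (bk > 0)).sum()),
    )
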
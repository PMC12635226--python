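"""Cell- and gene-level quality filters.

Cells are removed when they have fewer than ``min_genes_per_cell`` detected
genes or more than ``max_mito_fraction`` of their counts on mitochondrial
genes (strict inequalities: a cell with exactly 200 detected genes or
exactly 10% mitochondrial counts is kept).  Genes expressed in fewer than
``min_cells_per_gene`` of the surviving cells are then removed.  Everything
that was removed, and why, is recorded in a :class:`QCReport`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import AnalysisConfig, CellAnnotation, ExpressionMatrix

__all__ = ["QCReport", "detect_genes_per_cell", "mito_fraction", "apply_qc"]


@dataclass
class QCReport:
    n_cells_in: int
    n_cells_out: int
    n_genes_in: int
    n_genes_out: int
    removed_cells: list[tuple[str, str]]  # (cell_id, reason in {low_genes, high_mito, both})
    removed_genes: list[str]
    thresholds: dict

    def to_frame(self):
        import pandas as pd

        rows = [
            {"axis": "cell", "id": cid, "reason": reason}
            for cid, reason in self.removed_cells
        ] + [
            {"axis": "gene", "id": g, "reason": "low_prevalence"}
            for g in self.removed_genes
        ]
        return pd.DataFrame(rows, columns=["axis", "id", "reason"])


def detect_genes_per_cell(matrix: ExpressionMatrix) -> np.ndarray:
    """Number of genes with a nonzero count, per cell."""
    _require_raw(matrix)
    return (matrix.values > 0).sum(axis=0).astype(int)


def mito_fraction(matrix: ExpressionMatrix, mito_pattern: str = "MT-") -> np.ndarray:
    """Share of each cell's total counts on genes whose name starts with
    ``mito_pattern``; 0 for all-zero cells."""
    _require_raw(matrix)
    mask = np.array([g.startswith(mito_pattern) for g in matrix.gene_ids])
    if not mask.any():
        warnings.warn(f"no genes match mitochondrial prefix {mito_pattern!r}")
        return np.zeros(matrix.n_cells)
    totals = matrix.values.sum(axis=0)
    mito = matrix.values[mask].sum(axis=0)
    with np.errstate(invalid="ignore"):
        frac = np.where(totals > 0, mito / np.where(totals > 0, totals, 1.0), 0.0)
    return frac


def apply_qc(
    matrix: ExpressionMatrix,
    annotation: CellAnnotation,
    config: AnalysisConfig | None = None,
) -> tuple[ExpressionMatrix, CellAnnotation, QCReport]:
    """Filter cells, then genes, in one pass.

    Cell rule: with ``qc_rule="union"`` (default) a cell failing either the
    detected-gene or the mitochondrial criterion is removed; with
    ``"intersection"`` it must fail both.  The gene prevalence filter is
    evaluated on the cells that survive.
    """
    config = config or AnalysisConfig()
    _require_raw(matrix)
    if set(matrix.cell_ids) - set(annotation.cell_ids):
        raise ValueError("annotation does not cover every cell in the matrix")

    if matrix.n_cells == 0:
        report = QCReport(0, 0, matrix.n_genes, matrix.n_genes, [], [], _thresholds(config))
        return matrix.copy(), annotation.select(np.zeros(len(annotation), bool)), report

    detected = detect_genes_per_cell(matrix)
    frac = mito_fraction(matrix, config.mito_pattern)
    low = detected < config.min_genes_per_cell
    high = frac > config.max_mito_fraction
    drop_cell = (low | high) if config.qc_rule == "union" else (low & high)

    removed_cells = [
        (
            matrix.cell_ids[i],
            "both" if (low[i] and high[i]) else ("low_genes" if low[i] else "high_mito"),
        )
        for i in np.flatnonzero(drop_cell)
    ]
    keep_cell = ~drop_cell

    surviving = matrix.values[:, keep_cell]
    cells_expressing = (surviving > 0).sum(axis=1)
    drop_gene = cells_expressing < config.min_cells_per_gene
    removed_genes = [matrix.gene_ids[i] for i in np.flatnonzero(drop_gene)]
    keep_gene = ~drop_gene

    out = ExpressionMatrix(
        surviving[keep_gene],
        [g for g, k in zip(matrix.gene_ids, keep_gene) if k],
        [c for c, k in zip(matrix.cell_ids, keep_cell) if k],
        "raw",
    )
    order = {cid: i for i, cid in enumerate(annotation.cell_ids)}
    ann_keep = np.array(
        [order[c] for c in out.cell_ids], dtype=int
    )  # preserve matrix cell order
    ann_out = annotation.select(ann_keep)

    report = QCReport(
        n_cells_in=matrix.n_cells,
        n_cells_out=out.n_cells,
        n_genes_in=matrix.n_genes,
        n_genes_out=out.n_genes,
        removed_cells=removed_cells,
        removed_genes=removed_genes,
        thresholds=_thresholds(config),
    )
    return out, ann_out, report


def _thresholds(config: AnalysisConfig) -> dict:
    return {
        "min_genes_per_cell": config.min_genes_per_cell,
        "max_mito_fraction": config.max_mito_fraction,
        "min_cells_per_gene": config.min_cells_per_gene,
        "qc_rule": config.qc_rule,
    }


def _require_raw(matrix: ExpressionMatrix) -> None:
    if matrix.layer_tag != "raw":
        raise ValueError(f"QC operates on raw counts, got layer {matrix.layer_tag!r}")
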
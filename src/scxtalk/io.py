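"""Containers, file formats and run configuration.

The pipeline moves three kinds of tables around: a genes x cells expression
matrix (Matrix Market coordinate triplet with ``features.tsv`` /
``barcodes.tsv`` sidecars, the CellRanger convention), a per-cell annotation
table (cell id, cell subset, age group), and a ligand-receptor pair table.
All tabular output is TSV with a commented header block recording the
software version, the seed and the relevant configuration, so a permutation
analysis can be audited and re-run byte-identically.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

__all__ = [
    "AGE_GROUPS",
    "LAYERS",
    "FormatError",
    "ExpressionMatrix",
    "CellAnnotation",
    "LRPairTable",
    "AnalysisConfig",
    "read_matrix",
    "write_matrix",
    "read_annotation",
    "write_annotation",
    "read_lr_table",
    "write_lr_table",
    "normalize",
    "packaged_lr_table",
    "load_analysis_config",
    "write_table",
]

#: the two condition labels whose within-subset permutation defines the null
AGE_GROUPS = ("young", "old")

#: recognised expression layers
LAYERS = ("raw", "cp10k", "log1p_cp10k")

_CP10K_TARGET = 10_000.0


class FormatError(ValueError):
    """Raised when an on-disk file violates the expected format."""


def _check_unique(ids: Sequence[str], what: str, where: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))
        raise FormatError(f"duplicate {what} id {dup!r} in {where}")


@dataclass
class ExpressionMatrix:
    """A genes x cells expression matrix with one named layer.

    ``values`` is a dense float array of shape ``(len(gene_ids),
    len(cell_ids))``.  ``layer_tag`` records the scale: ``raw`` (non-negative
    integer counts), ``cp10k`` (counts scaled per cell to sum 10,000) or
    ``log1p_cp10k`` (natural log of cp10k + 1).
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    layer_tag: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        _check_unique(self.gene_ids, "gene", "ExpressionMatrix")
        _check_unique(self.cell_ids, "cell", "ExpressionMatrix")
        if self.layer_tag not in LAYERS:
            raise FormatError(f"unknown layer tag {self.layer_tag!r}")
        if np.any(self.values < 0):
            raise FormatError("expression values must be non-negative")
        if self.layer_tag == "raw" and not np.array_equal(
            self.values, np.floor(self.values)
        ):
            raise FormatError("raw layer must contain integer counts")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_row(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not present in matrix") from None

    def has_gene(self, gene: str) -> bool:
        return gene in self._gene_index

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), list(self.gene_ids), list(self.cell_ids), self.layer_tag
        )


@dataclass
class CellAnnotation:
    """Per-cell labels: cell subset (the permutation stratum) and age group."""

    cell_ids: np.ndarray
    subset: np.ndarray
    age_group: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.subset = np.asarray(self.subset, dtype=object)
        self.age_group = np.asarray(self.age_group, dtype=object)
        n = len(self.cell_ids)
        if len(self.subset) != n or len(self.age_group) != n:
            raise FormatError("annotation columns have unequal lengths")
        _check_unique(list(self.cell_ids), "cell", "CellAnnotation")
        bad = set(self.age_group) - set(AGE_GROUPS)
        if bad:
            raise FormatError(
                f"age_group values {sorted(bad)} not in {AGE_GROUPS}"
            )

    def __len__(self) -> int:
        return len(self.cell_ids)

    @property
    def subsets(self) -> list[str]:
        """Unique subset labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.subset:
            seen.setdefault(s, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "subset": self.subset,
                "age_group": self.age_group,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CellAnnotation":
        missing = {"cell_id", "subset", "age_group"} - set(df.columns)
        if missing:
            raise FormatError(f"annotation table lacks columns {sorted(missing)}")
        return cls(
            df["cell_id"].to_numpy(),
            df["subset"].to_numpy(),
            df["age_group"].to_numpy(),
        )

    def select(self, keep: np.ndarray) -> "CellAnnotation":
        return CellAnnotation(
            self.cell_ids[keep], self.subset[keep], self.age_group[keep]
        )


@dataclass
class LRPairTable:
    """Ordered ligand->receptor gene pairs with a provenance tag.

    Order matters: A->B (A the ligand) is a different interaction from B->A.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"ligand", "receptor"} - set(self.records.columns)
        if missing:
            raise FormatError(f"LR table lacks columns {sorted(missing)}")
        if "source" not in self.records.columns:
            self.records = self.records.assign(source="user")
        self.records = self.records[["ligand", "receptor", "source"]].reset_index(
            drop=True
        )
        if (
            self.records[["ligand", "receptor"]]
            .astype(str)
            .apply(lambda c: c.str.len() == 0)
            .to_numpy()
            .any()
        ):
            raise FormatError("LR table contains empty gene ids")
        if self.records.duplicated(subset=["ligand", "receptor"]).any():
            raise FormatError("LR table contains duplicate ordered pairs")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], source: str = "user"
    ) -> "LRPairTable":
        pairs = list(pairs)
        return cls(
            pd.DataFrame(
                {
                    "ligand": [p[0] for p in pairs],
                    "receptor": [p[1] for p in pairs],
                    "source": source,
                }
            )
        )

    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.records["ligand"], self.records["receptor"]))


@dataclass
class AnalysisConfig:
    """All thresholds and switches of the downstream analysis.

    Defaults follow the study conventions: 1,000 permutations with a 0.01
    cutoff for crosstalk; marker flagging at corrected p < 0.01 and fold
    change > 1.5 (Bonferroni); aging-gene flagging at p < 0.05; cells with
    fewer than 200 detected genes or more than 10% mitochondrial counts
    removed; genes seen in fewer than 3 cells removed.
    """

    n_permutations: int = 1000
    alpha_crosstalk: float = 0.01
    marker_alpha: float = 0.01
    marker_fc: float = 1.5
    aging_gene_alpha: float = 0.05
    min_genes_per_cell: int = 200
    max_mito_fraction: float = 0.10
    min_cells_per_gene: int = 3
    normalization: str = "cp10k"
    seed: int = 0
    # switches beyond the headline thresholds
    qc_rule: str = "union"            # {"union", "intersection"}
    mito_pattern: str = "MT-"         # gene-name prefix marking mitochondrial genes
    fc_mode: str = "linear_ratio"     # {"linear_ratio", "log2_diff"}
    aging_use_bh: bool = False        # flag aging genes on BH-adjusted p instead of raw
    crosstalk_pseudo: bool = False    # additionally report (n+1)/(N+1)

    def __post_init__(self) -> None:
        for name in ("alpha_crosstalk", "marker_alpha", "aging_gene_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0,1), got {v}")
        for name in (
            "n_permutations",
            "marker_fc",
            "min_genes_per_cell",
            "max_mito_fraction",
            "min_cells_per_gene",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.normalization not in LAYERS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.qc_rule not in ("union", "intersection"):
            raise ValueError(f"unknown qc_rule {self.qc_rule!r}")
        if self.fc_mode not in ("linear_ratio", "log2_diff"):
            raise ValueError(f"unknown fc_mode {self.fc_mode!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_analysis_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a flat key-value YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a flat key-value mapping")
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    return AnalysisConfig(**data)


# ---------------------------------------------------------------------------
# Matrix Market triplet + sidecars


def read_matrix(
    path_matrix: str | Path,
    path_features: str | Path,
    path_barcodes: str | Path,
    *,
    transpose: bool = False,
    layer_tag: str = "raw",
) -> ExpressionMatrix:
    """Read an MTX coordinate triplet with features/barcodes sidecars.

    Genes are assumed to be rows on disk (the CellRanger convention); pass
    ``transpose=True`` for matrices stored cells x genes.  The sidecar line
    counts must match the matrix dimensions.
    """
    try:
        sparse = scipy.io.mmread(str(path_matrix))
    except Exception as exc:  # malformed header / body
        raise FormatError(f"{path_matrix}: not a readable MatrixMarket file ({exc})")
    dense = np.asarray(sparse.todense() if scipy.sparse.issparse(sparse) else sparse)
    if transpose:
        dense = dense.T
    genes = _read_id_column(path_features)
    cells = _read_id_column(path_barcodes)
    if len(genes) != dense.shape[0]:
        raise FormatError(
            f"{path_features}: {len(genes)} lines but matrix declares "
            f"{dense.shape[0]} gene rows"
        )
    if len(cells) != dense.shape[1]:
        raise FormatError(
            f"{path_barcodes}: {len(cells)} lines but matrix declares "
            f"{dense.shape[1]} cell columns"
        )
    if np.any(dense < 0):
        g, c = np.argwhere(dense < 0)[0]
        raise FormatError(
            f"{path_matrix}: negative value at gene line {g + 1}, cell column {c + 1}"
        )
    _check_unique(genes, "gene", str(path_features))
    _check_unique(cells, "cell", str(path_barcodes))
    return ExpressionMatrix(dense, genes, cells, layer_tag=layer_tag)


def _read_id_column(path: str | Path) -> list[str]:
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            ids.append(line.split("\t")[0])
    return ids


def write_matrix(
    matrix: ExpressionMatrix,
    path_matrix: str | Path,
    path_features: str | Path,
    path_barcodes: str | Path,
) -> None:
    """Write the matrix as an MTX triplet (1-based coordinates, genes as rows)."""
    coo = scipy.sparse.coo_matrix(matrix.values)
    field = "integer" if matrix.layer_tag == "raw" else "real"
    if field == "integer":
        coo = coo.astype(np.int64)
    scipy.io.mmwrite(str(path_matrix), coo, field=field)
    with open(path_features, "w") as fh:
        for g in matrix.gene_ids:
            fh.write(f"{g}\t{g}\n")
    with open(path_barcodes, "w") as fh:
        for c in matrix.cell_ids:
            fh.write(f"{c}\n")


# ---------------------------------------------------------------------------
# TSV tables


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_annotation(path: str | Path) -> CellAnnotation:
    """Read a cell annotation TSV (columns cell_id, subset, age_group)."""
    return CellAnnotation.from_frame(_read_tsv(path))


def write_annotation(
    annotation: CellAnnotation, path: str | Path, **header_kwargs
) -> None:
    write_table(annotation.to_frame(), path, **header_kwargs)


def read_lr_table(path: str | Path) -> LRPairTable:
    """Read a ligand-receptor pair TSV; duplicate ordered pairs are collapsed
    with a warning.  Columns ``ligand`` and ``receptor`` are required,
    ``source`` is optional.
    """
    df = _read_tsv(path)
    missing = {"ligand", "receptor"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: LR table lacks columns {sorted(missing)}")
    n_before = len(df)
    df = df.drop_duplicates(subset=["ligand", "receptor"], keep="first")
    if len(df) < n_before:
        warnings.warn(
            f"{path}: collapsed {n_before - len(df)} duplicate ligand-receptor pairs"
        )
    return LRPairTable(df.reset_index(drop=True))


def write_lr_table(table: LRPairTable, path: str | Path, **header_kwargs) -> None:
    write_table(table.records, path, **header_kwargs)


def packaged_lr_table() -> LRPairTable:
    """The packaged literature-derived ligand-receptor fixture table."""
    ref = importlib.resources.files("scxtalk").joinpath("data/lr_fixture.tsv")
    with importlib.resources.as_file(ref) as path:
        return read_lr_table(path)


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    *,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
    extra: dict | None = None,
) -> None:
    """Write a TSV with a commented audit header (version, seed, config).

    The header carries no timestamps so repeated runs with identical inputs
    produce byte-identical files.
    """
    from . import __version__

    lines = [f"# scxtalk {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        for k, v in config.to_dict().items():
            lines.append(f"# config.{k}: {v}")
    for k, v in (extra or {}).items():
        lines.append(f"# {k}: {v}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Normalization


def normalize(matrix: ExpressionMatrix, mode: str = "cp10k") -> ExpressionMatrix:
    """Rescale a raw counts matrix.

    ``cp10k`` scales every cell column to a total of 10,000 counts;
    ``log1p_cp10k`` additionally applies ``log(1 + x)``; ``raw`` is the
    identity.  All-zero cells are left all-zero with a warning rather than
    dividing by zero.
    """
    if mode not in LAYERS:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if matrix.layer_tag != "raw":
        raise ValueError(
            f"normalize expects the raw layer, got {matrix.layer_tag!r}"
        )
    if mode == "raw":
        return matrix.copy()
    totals = matrix.values.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero cell(s) left unnormalized")
    safe = np.where(zero, 1.0, totals)
    values = matrix.values * (_CP10K_TARGET / safe)
    if mode == "log1p_cp10k":
        values = np.log1p(values)
    return ExpressionMatrix(values, list(matrix.gene_ids), list(matrix.cell_ids), mode)
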
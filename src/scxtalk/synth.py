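"""Synthetic single-cell count data with planted ligand-receptor effects.

The generator emulates the statistical structure the crosstalk analysis
assumes: several cell subsets sampled in two age groups, overdispersed
(gamma-Poisson) counts with per-cell library-size variation, a block of
mitochondrial genes recognisable by name prefix, optional planted
low-quality cells, and planted age-specific mean shifts on ligand and
receptor genes.  Every planted effect is returned in a ground-truth table so
downstream recovery can be scored exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import (
    AGE_GROUPS,
    CellAnnotation,
    ExpressionMatrix,
    LRPairTable,
    write_annotation,
    write_lr_table,
    write_matrix,
    write_table,
)

__all__ = [
    "ConfigurationError",
    "PlantedEffect",
    "SimConfig",
    "SyntheticTruth",
    "generate_dataset",
    "make_null_dataset",
    "write_dataset",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class PlantedEffect:
    """An age-specific ligand/receptor mean shift.

    The ligand gene's mean is multiplied by ``fold`` in the
    (sender_subset, age_group) cells and the receptor gene's mean by ``fold``
    in the (receiver_subset, age_group) cells.
    """

    ligand: str
    receptor: str
    sender_subset: str
    receiver_subset: str
    age_group: str
    fold: float


@dataclass
class SyntheticTruth:
    """Ground truth: the planted effects, verbatim."""

    records: list[PlantedEffect]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([dataclasses.asdict(r) for r in self.records]) if (
            self.records
        ) else pd.DataFrame(
            columns=[
                "ligand",
                "receptor",
                "sender_subset",
                "receiver_subset",
                "age_group",
                "fold",
            ]
        )


@dataclass
class SimConfig:
    """Parameters of the synthetic dataset.

    ``baseline_mean`` is the expected raw count per gene per cell before
    gene-level and cell-level variation; ``dispersion`` is the
    negative-binomial size parameter (smaller = more overdispersed).
    ``gene_mean_sigma`` and ``libsize_sigma`` are the log-normal sigmas of
    the per-gene mean spread and the per-cell library-size factor; set them
    to 0 for exactly identical means.  Planted low-quality cells either keep
    only ``lowquality_gene_fraction`` of genes (capped so fewer than 200 are
    detectable) or have their mitochondrial means inflated to roughly a 40%
    share, or both.
    """

    n_subsets: int = 3
    cells_per_subset_per_age: int = 100
    n_genes: int = 500
    n_mito_genes: int = 10
    baseline_mean: float = 2.0
    dispersion: float = 5.0
    gene_mean_sigma: float = 0.5
    libsize_sigma: float = 0.3
    planted_effects: tuple[PlantedEffect, ...] = ()
    n_decoy_pairs: int = 30
    n_lowquality_cells: int = 0
    lowquality_gene_fraction: float = 0.05
    mito_prefix: str = "MT-"
    subset_names: tuple[str, ...] | None = None
    gene_names: tuple[str, ...] | None = None
    seed: int = 0

    # detected-gene ceiling for planted low-quality cells (the conventional
    # 200-gene QC threshold, minus one so the cells fail it by construction)
    _LOWQ_MAX_DETECTED = 199
    _LOWQ_MITO_SHARE = 0.40

    def __post_init__(self) -> None:
        self.planted_effects = tuple(
            e if isinstance(e, PlantedEffect) else PlantedEffect(*e)
            for e in self.planted_effects
        )
        for name in ("n_subsets", "cells_per_subset_per_age", "n_genes"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("n_mito_genes", "n_decoy_pairs", "n_lowquality_cells"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_mito_genes > self.n_genes:
            raise ConfigurationError("n_mito_genes exceeds n_genes")
        for name in ("baseline_mean", "dispersion"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0 < self.lowquality_gene_fraction < 1:
            raise ConfigurationError("lowquality_gene_fraction must lie in (0,1)")
        for e in self.planted_effects:
            if e.fold <= 0:
                raise ConfigurationError(f"planted fold must be positive, got {e.fold}")
            if e.age_group not in AGE_GROUPS:
                raise ConfigurationError(
                    f"planted age_group {e.age_group!r} not in {AGE_GROUPS}"
                )
        if self.subset_names is not None and len(self.subset_names) != self.n_subsets:
            raise ConfigurationError("subset_names length must equal n_subsets")

    # -- naming ----------------------------------------------------------
    def make_subset_names(self) -> list[str]:
        if self.subset_names is not None:
            return list(self.subset_names)
        return [f"subset{i + 1}" for i in range(self.n_subsets)]

    def make_gene_names(self) -> list[str]:
        n_ordinary = self.n_genes - self.n_mito_genes
        names = [f"MT-{i + 1}" for i in range(self.n_mito_genes)]
        ordinary = [f"G{i + 1:05d}" for i in range(n_ordinary)]
        if self.gene_names is not None:
            if len(self.gene_names) > n_ordinary:
                raise ConfigurationError(
                    "gene_names longer than the non-mitochondrial panel"
                )
            ordinary[: len(self.gene_names)] = list(self.gene_names)
            if len(set(ordinary)) != len(ordinary):
                raise ConfigurationError("gene_names collide with generated names")
        return names + ordinary


def _validate_effects(config: SimConfig, genes: list[str], subsets: list[str]) -> None:
    gene_set, subset_set = set(genes), set(subsets)
    for e in config.planted_effects:
        for g in (e.ligand, e.receptor):
            if g not in gene_set:
                raise ConfigurationError(f"planted effect names unknown gene {g!r}")
        for s in (e.sender_subset, e.receiver_subset):
            if s not in subset_set:
                raise ConfigurationError(f"planted effect names unknown subset {s!r}")


def generate_dataset(
    config: SimConfig,
) -> tuple[ExpressionMatrix, CellAnnotation, LRPairTable, SyntheticTruth]:
    """Draw one synthetic dataset.

    Counts are negative binomial with mean ``mu[g, c] = baseline_mean *
    gene_factor[g] * lib_factor[c]`` (both factors log-normal with unit
    mean), multiplied by the planted fold for cells in an affected
    (subset, age group).  The returned pair table holds the planted pairs
    plus ``n_decoy_pairs`` decoys drawn from untouched genes.  Identical
    configs (including seed) yield byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    subsets = config.make_subset_names()
    genes = config.make_gene_names()
    _validate_effects(config, genes, subsets)
    gene_index = {g: i for i, g in enumerate(genes)}

    n_regular = config.n_subsets * 2 * config.cells_per_subset_per_age
    n_cells = n_regular + config.n_lowquality_cells

    cell_subset = np.empty(n_cells, dtype=object)
    cell_age = np.empty(n_cells, dtype=object)
    pos = 0
    for s in subsets:
        for age in AGE_GROUPS:
            end = pos + config.cells_per_subset_per_age
            cell_subset[pos:end] = s
            cell_age[pos:end] = age
            pos = end
    # low-quality cells: subset cycles deterministically, age drawn at random
    # so age labels stay exchangeable within each subset
    for k in range(config.n_lowquality_cells):
        cell_subset[n_regular + k] = subsets[k % len(subsets)]
        cell_age[n_regular + k] = AGE_GROUPS[rng.integers(2)]
    cell_ids = [f"C{i + 1:06d}" for i in range(n_cells)]

    # unit-mean log-normal factors
    gs, ls = config.gene_mean_sigma, config.libsize_sigma
    gene_factor = (
        np.exp(rng.normal(-0.5 * gs * gs, gs, size=config.n_genes))
        if gs > 0
        else np.ones(config.n_genes)
    )
    lib_factor = (
        np.exp(rng.normal(-0.5 * ls * ls, ls, size=n_cells))
        if ls > 0
        else np.ones(n_cells)
    )
    mu = config.baseline_mean * np.outer(gene_factor, lib_factor)

    for e in config.planted_effects:
        send = (cell_subset == e.sender_subset) & (cell_age == e.age_group)
        recv = (cell_subset == e.receiver_subset) & (cell_age == e.age_group)
        mu[gene_index[e.ligand], send] *= e.fold
        mu[gene_index[e.receptor], recv] *= e.fold

    # plant low-quality cells by editing their mean vectors
    mito_rows = np.array(
        [i for i, g in enumerate(genes) if g.startswith(config.mito_prefix)], dtype=int
    )
    reasons = ("low_genes", "high_mito", "both")
    for k in range(config.n_lowquality_cells):
        c = n_regular + k
        reason = reasons[k % 3]
        if reason in ("high_mito", "both") and len(mito_rows) == 0:
            raise ConfigurationError(
                "cannot plant high-mito cells without mitochondrial genes"
            )
        if reason in ("low_genes", "both"):
            n_keep = min(
                int(round(config.lowquality_gene_fraction * config.n_genes)),
                config._LOWQ_MAX_DETECTED,
            )
            keep = rng.choice(config.n_genes, size=max(n_keep, 1), replace=False)
            mask = np.ones(config.n_genes, dtype=bool)
            mask[keep] = False
            mu[mask, c] = 0.0
        if reason in ("high_mito", "both"):
            mito_total = mu[mito_rows, c].sum()
            other_total = mu[:, c].sum() - mito_total
            share = config._LOWQ_MITO_SHARE
            if mito_total > 0 and other_total > 0:
                mu[mito_rows, c] *= (share / (1 - share)) * other_total / mito_total

    # gamma-Poisson draw: NB(size=dispersion, mean=mu)
    p = config.dispersion / (config.dispersion + np.maximum(mu, 1e-300))
    counts = np.where(mu > 0, rng.negative_binomial(config.dispersion, p), 0)

    matrix = ExpressionMatrix(counts.astype(float), genes, cell_ids, "raw")
    annotation = CellAnnotation(np.array(cell_ids, dtype=object), cell_subset, cell_age)

    lr_table = _build_pair_table(config, rng, genes, mito_rows)
    truth = SyntheticTruth(list(config.planted_effects))
    return matrix, annotation, lr_table, truth


def _build_pair_table(
    config: SimConfig,
    rng: np.random.Generator,
    genes: list[str],
    mito_rows: np.ndarray,
) -> LRPairTable:
    """Planted pairs plus decoy pairs over untouched non-mitochondrial genes."""
    import pandas as pd

    planted_pairs = []
    used: set[str] = set()
    for e in config.planted_effects:
        if (e.ligand, e.receptor) not in {(p[0], p[1]) for p in planted_pairs}:
            planted_pairs.append((e.ligand, e.receptor))
        used.update((e.ligand, e.receptor))
    candidates = [
        g
        for i, g in enumerate(genes)
        if g not in used and i not in set(mito_rows.tolist())
    ]
    need = 2 * config.n_decoy_pairs
    if need > len(candidates):
        raise ConfigurationError(
            f"n_decoy_pairs={config.n_decoy_pairs} needs {need} free genes, "
            f"only {len(candidates)} available"
        )
    chosen = rng.choice(len(candidates), size=need, replace=False)
    decoys = [
        (candidates[chosen[2 * i]], candidates[chosen[2 * i + 1]])
        for i in range(config.n_decoy_pairs)
    ]
    df = pd.DataFrame(
        {
            "ligand": [p[0] for p in planted_pairs] + [d[0] for d in decoys],
            "receptor": [p[1] for p in planted_pairs] + [d[1] for d in decoys],
            "source": ["planted"] * len(planted_pairs) + ["decoy"] * len(decoys),
        }
    )
    return LRPairTable(df)


def make_null_dataset(
    config: SimConfig,
) -> tuple[ExpressionMatrix, CellAnnotation, LRPairTable]:
    """A dataset whose age labels are exchangeable within every subset.

    Requires an effect-free configuration; young and old cells are then
    drawn from the identical generative law, so any age-label signal found
    downstream is a false positive by construction.
    """
    if config.planted_effects:
        raise ConfigurationError("make_null_dataset requires planted_effects = ()")
    matrix, annotation, lr_table, _ = generate_dataset(config)
    return matrix, annotation, lr_table


def write_dataset(
    outdir: str | Path,
    matrix: ExpressionMatrix,
    annotation: CellAnnotation,
    lr_table: LRPairTable,
    truth: SyntheticTruth | None = None,
    *,
    seed: int | None = None,
) -> None:
    """Write matrix.mtx + features.tsv + barcodes.tsv, annotation.tsv,
    lr_pairs.tsv and (if given) truth.tsv under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(
        matrix,
        outdir / "matrix.mtx",
        outdir / "features.tsv",
        outdir / "barcodes.tsv",
    )
    write_annotation(annotation, outdir / "annotation.tsv", seed=seed)
    write_lr_table(lr_table, outdir / "lr_pairs.tsv", seed=seed)
    if truth is not None:
        write_table(truth.to_frame(), outdir / "truth.tsv", seed=seed)
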
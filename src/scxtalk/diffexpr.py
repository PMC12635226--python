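"""Wilcoxon rank-sum differential expression with two flagging rules.

Cluster markers: each gene is tested group-vs-rest; a gene is flagged when
the Bonferroni-corrected p-value is below ``marker_alpha`` (default 0.01)
and the fold change exceeds ``marker_fc`` (default 1.5).

Aging-associated genes: each gene is tested old-vs-young within one cell
subset; Benjamini-Hochberg adjusted p-values are reported alongside, and a
gene is flagged when the raw p-value is below ``aging_gene_alpha`` (default
0.05; a config switch flags on the BH-adjusted value instead).

The rank-sum test uses midranks for ties, exact enumeration when both
groups have at most 8 observations and there are no ties, and the normal
approximation with tie correction otherwise (two-sided throughout).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AGE_GROUPS, AnalysisConfig, CellAnnotation, ExpressionMatrix

__all__ = [
    "MarkerRecord",
    "AgingGeneRecord",
    "wilcoxon_test",
    "bonferroni",
    "benjamini_hochberg",
    "find_markers",
    "aging_genes",
]

_EPS = 1e-9  # pseudocount protecting fold-change ratios

_EXACT_MAX_N = 8


class MarkerRecord(NamedTuple):
    gene: str
    group: str
    p_raw: float
    p_adj: float
    fold_change: float
    flagged: bool


class AgingGeneRecord(NamedTuple):
    gene: str
    subset: str
    p_raw: float
    p_bh: float
    direction: str  # up_in_old | down_in_old
    flagged: bool


def wilcoxon_test(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns the Mann-Whitney U statistic of the first sample and the
    two-sided p-value.  Exact when both samples have at most 8 values and no
    ties are present; normal approximation with tie correction otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("wilcoxon_test requires two nonempty samples")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        # every observation tied: the statistic is at its null expectation
        return float(a.size * b.size / 2), 1.0
    method = _choose_method(a.size, b.size, pooled)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _choose_method(na: int, nb: int, pooled: np.ndarray) -> str:
    if na <= _EXACT_MAX_N and nb <= _EXACT_MAX_N and np.unique(pooled).size == pooled.size:
        return "exact"
    return "asymptotic"


def _validate_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bonferroni(p) -> np.ndarray:
    """Family-wise Bonferroni correction: min(1, m * p)."""
    p = _validate_p(p)
    if p.size == 0:
        return p
    return multipletests(p, method="bonferroni")[1]


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini-Hochberg step-up false-discovery-rate adjustment."""
    p = _validate_p(p)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _batch_wilcoxon(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Two-sided asymptotic p-values per gene (rows of A vs rows of B)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(
            A, B, alternative="two-sided", method="asymptotic", axis=1
        )
    p = np.asarray(res.pvalue, dtype=float)
    # genes constant across both groups have zero tie-corrected variance
    pooled = np.concatenate([A, B], axis=1)
    constant = pooled.min(axis=1) == pooled.max(axis=1)
    p[constant] = 1.0
    return p


def _linear_means(matrix: ExpressionMatrix, mask: np.ndarray) -> np.ndarray:
    """Per-gene means on the linear scale (log layer is de-logged first)."""
    vals = matrix.values[:, mask]
    if matrix.layer_tag == "log1p_cp10k":
        vals = np.expm1(vals)
    return vals.mean(axis=1)


def _fold_change(mean_a: np.ndarray, mean_b: np.ndarray, mode: str) -> np.ndarray:
    ratio = (mean_a + _EPS) / (mean_b + _EPS)
    if mode == "log2_diff":
        return np.log2(ratio)
    return ratio


def _fc_passes(fc: np.ndarray, threshold: float, mode: str) -> np.ndarray:
    if mode == "log2_diff":
        return np.exp2(fc) > threshold
    return fc > threshold


def find_markers(
    matrix: ExpressionMatrix,
    annotation: CellAnnotation,
    group: str,
    config: AnalysisConfig | None = None,
) -> list[MarkerRecord]:
    """Group-vs-rest marker test for one cell subset.

    Expects a normalized layer.  Fold change is the ratio of linear-scale
    means (group over rest) with a small pseudocount; flagging follows the
    corrected-p < ``marker_alpha`` AND fold change > ``marker_fc`` rule,
    with Bonferroni correction over the genes tested.
    """
    config = config or AnalysisConfig()
    in_group = annotation.subset == group
    if in_group.sum() < 2:
        raise ValueError(f"group {group!r} has fewer than 2 cells")
    if (~in_group).sum() == 0:
        raise ValueError("no cells outside the group to compare against")
    _check_alignment(matrix, annotation)

    p_raw = _batch_wilcoxon(matrix.values[:, in_group], matrix.values[:, ~in_group])
    p_adj = bonferroni(p_raw)
    fc = _fold_change(
        _linear_means(matrix, in_group),
        _linear_means(matrix, ~in_group),
        config.fc_mode,
    )
    passes = _fc_passes(fc, config.marker_fc, config.fc_mode)
    return [
        MarkerRecord(
            gene=g,
            group=group,
            p_raw=float(p_raw[i]),
            p_adj=float(p_adj[i]),
            fold_change=float(fc[i]),
            flagged=bool(p_adj[i] < config.marker_alpha and passes[i]),
        )
        for i, g in enumerate(matrix.gene_ids)
    ]


def aging_genes(
    matrix: ExpressionMatrix,
    annotation: CellAnnotation,
    subset: str,
    config: AnalysisConfig | None = None,
) -> list[AgingGeneRecord]:
    """Old-vs-young test per gene within one cell subset.

    BH-adjusted p-values are reported for every gene; the flag uses the raw
    p-value against ``aging_gene_alpha`` unless ``config.aging_use_bh``.
    """
    config = config or AnalysisConfig()
    _check_alignment(matrix, annotation)
    in_subset = annotation.subset == subset
    if not in_subset.any():
        raise ValueError(f"subset {subset!r} has no cells")
    old = in_subset & (annotation.age_group == "old")
    young = in_subset & (annotation.age_group == "young")
    for name, mask in (("old", old), ("young", young)):
        if not mask.any():
            raise ValueError(f"subset {subset!r} has no {name} cells")

    p_raw = _batch_wilcoxon(matrix.values[:, old], matrix.values[:, young])
    p_bh = benjamini_hochberg(p_raw)
    up = _linear_means(matrix, old) >= _linear_means(matrix, young)
    flag_p = p_bh if config.aging_use_bh else p_raw
    return [
        AgingGeneRecord(
            gene=g,
            subset=subset,
            p_raw=float(p_raw[i]),
            p_bh=float(p_bh[i]),
            direction="up_in_old" if up[i] else "down_in_old",
            flagged=bool(flag_p[i] < config.aging_gene_alpha),
        )
        for i, g in enumerate(matrix.gene_ids)
    ]


def _check_alignment(matrix: ExpressionMatrix, annotation: CellAnnotation) -> None:
    if len(annotation) != matrix.n_cells or not np.array_equal(
        annotation.cell_ids, np.array(matrix.cell_ids, dtype=object)
    ):
        raise ValueError("annotation is not aligned with the matrix cells")
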
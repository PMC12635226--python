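"""Ligand-receptor interaction scoring with an age-label permutation null.

For a ligand-receptor pair (l, r), a sender subset i, a receiver subset j
and an age group, the interaction score is

    S = mean expression of l over the (i, age) cells
        x mean expression of r over the (j, age) cells.

The null distribution is built by randomly permuting the age-group label
within each cell subset (subset membership never changes) N times and
recomputing the score S_p each time.  The p-value is p = n / N, where n
counts permuted scores at least as large as the observed one ("as or
higher", so ties count and the test is one-sided for up-regulation in the
scored age group).  Interactions with p <= alpha (default 0.01) are flagged
significant.  One shared permutation per iteration is applied to every
subset and reused across all pairs, giving a coherent joint null and O(N)
shuffles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .io import (
    AGE_GROUPS,
    AnalysisConfig,
    CellAnnotation,
    ExpressionMatrix,
    LRPairTable,
)

__all__ = [
    "InteractionRecord",
    "CrosstalkResult",
    "group_mean",
    "interaction_score",
    "permute_age_labels",
    "permutation_pvalue",
    "run_crosstalk",
]

# relative tie tolerance: permuted group means of the same multiset can
# differ from the observed ones in the last float bit, which must still
# count as a tie ("as or higher")
_TIE_RTOL = 1e-9


class InteractionRecord(NamedTuple):
    ligand: str
    receptor: str
    sender: str
    receiver: str
    age_group: str
    S: float
    n: int
    N: int
    p: float
    significant: bool
    p_pseudo: float | None = None


@dataclass
class CrosstalkResult:
    records: list[InteractionRecord]
    skipped_pairs: list[tuple[str, str, str]]  # (ligand, receptor, reason)

    def to_frame(self):
        import pandas as pd

        cols = list(InteractionRecord._fields)
        df = pd.DataFrame(self.records, columns=cols)
        if df["p_pseudo"].isna().all():
            df = df.drop(columns=["p_pseudo"])
        return df

    def skipped_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.skipped_pairs, columns=["ligand", "receptor", "reason"]
        )


def group_mean(
    matrix: ExpressionMatrix,
    annotation: CellAnnotation,
    subset: str,
    age_group: str,
    gene: str,
) -> float:
    """Arithmetic mean of one gene over the cells of one (subset, age group)."""
    _check_alignment(matrix, annotation)
    mask = (annotation.subset == subset) & (annotation.age_group == age_group)
    if not mask.any():
        raise ValueError(f"no cells in subset {subset!r}, age group {age_group!r}")
    return float(matrix.values[matrix.gene_row(gene), mask].mean())


def interaction_score(
    matrix: ExpressionMatrix,
    annotation: CellAnnotation,
    pair: tuple[str, str],
    sender: str,
    receiver: str,
    age_group: str,
) -> float:
    """S = mean(ligand | sender, age) x mean(receptor | receiver, age)."""
    ligand, receptor = pair
    return group_mean(matrix, annotation, sender, age_group, ligand) * group_mean(
        matrix, annotation, receiver, age_group, receptor
    )


def permute_age_labels(
    annotation: CellAnnotation, seed: int | np.random.Generator = 0
) -> CellAnnotation:
    """Uniformly shuffle the age labels within each subset.

    Per-subset young/old counts are preserved exactly and subset labels are
    untouched.  A subset containing a single age group is left unchanged
    with a warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    new_age = annotation.age_group.copy()
    for s in annotation.subsets:
        idx = np.flatnonzero(annotation.subset == s)
        labels = annotation.age_group[idx]
        if len(set(labels)) < 2:
            warnings.warn(f"subset {s!r} has a single age group; labels unchanged")
            continue
        new_age[idx] = rng.permutation(labels)
    return CellAnnotation(annotation.cell_ids.copy(), annotation.subset.copy(), new_age)


# ---------------------------------------------------------------------------
# Batched permutation engine


@dataclass
class _Engine:
    """Shared state for scoring many records under one permutation stream."""

    X: np.ndarray                 # needed genes x cells
    subset_codes: np.ndarray      # per cell
    age_codes: np.ndarray         # per cell, 0=young 1=old
    subsets: list[str]
    subset_slices: list[np.ndarray] = field(default_factory=list)
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        n_groups = 2 * len(self.subsets)
        self.subset_slices = [
            np.flatnonzero(self.subset_codes == k) for k in range(len(self.subsets))
        ]
        group = 2 * self.subset_codes + self.age_codes
        self.counts = np.bincount(group, minlength=n_groups).astype(float)
        if np.any(self.counts == 0):
            k = int(np.argmin(self.counts))
            raise ValueError(
                f"subset {self.subsets[k // 2]!r} has no "
                f"{AGE_GROUPS[k % 2]} cells"
            )

    def group_means(self, age_codes: np.ndarray) -> np.ndarray:
        """Needed-genes x groups mean matrix for one label assignment."""
        n_groups = 2 * len(self.subsets)
        group = 2 * self.subset_codes + age_codes
        onehot = np.zeros((self.X.shape[1], n_groups))
        onehot[np.arange(self.X.shape[1]), group] = 1.0
        return (self.X @ onehot) / self.counts

    def permuted_ages(self, rng: np.random.Generator) -> np.ndarray:
        perm = self.age_codes.copy()
        for idx in self.subset_slices:
            perm[idx] = rng.permutation(perm[idx])
        return perm


def _record_index(
    pairs: Sequence[tuple[str, str]],
    gene_rows: dict[str, int],
    n_subsets: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[tuple[int, int, int, int]]]:
    """Flatten (pair, sender, receiver, age) into parallel index arrays."""
    lig_rows, rec_rows, send_grp, recv_grp = [], [], [], []
    meta = []
    for pi, (lig, rec) in enumerate(pairs):
        for si in range(n_subsets):
            for ri in range(n_subsets):
                for ai in range(2):
                    lig_rows.append(gene_rows[lig])
                    rec_rows.append(gene_rows[rec])
                    send_grp.append(2 * si + ai)
                    recv_grp.append(2 * ri + ai)
                    meta.append((pi, si, ri, ai))
    return (
        np.array(lig_rows),
        np.array(rec_rows),
        np.array(send_grp),
        np.array(recv_grp),
        meta,
    )


def run_crosstalk(
    matrix: ExpressionMatrix,
    annotation: CellAnnotation,
    lr_table: LRPairTable,
    config: AnalysisConfig | None = None,
) -> CrosstalkResult:
    """Score every pair x ordered (sender, receiver) x age group.

    Expects an already QC'd and normalized matrix.  Pairs with a gene
    missing from the matrix are reported in ``skipped_pairs`` rather than
    scored.  The same N sampled within-subset permutations are shared by all
    records; p = n/N exactly, and ``significant`` means p <= alpha.
    """
    config = config or AnalysisConfig()
    _check_alignment(matrix, annotation)

    skipped: list[tuple[str, str, str]] = []
    pairs: list[tuple[str, str]] = []
    for lig, rec in lr_table.pairs():
        missing = [g for g in (lig, rec) if not matrix.has_gene(g)]
        if missing:
            skipped.append((lig, rec, f"missing gene(s): {','.join(missing)}"))
        else:
            pairs.append((lig, rec))
    if not pairs:
        if len(lr_table):
            warnings.warn("no ligand-receptor pair could be scored")
        return CrosstalkResult([], skipped)

    complete = [
        s
        for s in annotation.subsets
        if len(set(annotation.age_group[annotation.subset == s])) == 2
    ]
    dropped = [s for s in annotation.subsets if s not in complete]
    if dropped:
        warnings.warn(
            f"subset(s) {dropped} lack one age group and are excluded from scoring"
        )
    if not complete:
        warnings.warn("no subset has both age groups; nothing to score")
        return CrosstalkResult([], skipped)
    keep = np.isin(annotation.subset.astype(str), complete)
    if not keep.all():
        col_keep = np.flatnonzero(keep)
        matrix = ExpressionMatrix(
            matrix.values[:, col_keep],
            list(matrix.gene_ids),
            [matrix.cell_ids[i] for i in col_keep],
            matrix.layer_tag,
        )
        annotation = annotation.select(col_keep)

    subsets = annotation.subsets
    subset_code = {s: k for k, s in enumerate(subsets)}
    subset_codes = np.array([subset_code[s] for s in annotation.subset])
    age_codes = np.array([AGE_GROUPS.index(a) for a in annotation.age_group])

    needed = sorted({g for p in pairs for g in p}, key=matrix.gene_row)
    rows = {g: i for i, g in enumerate(needed)}
    X = matrix.values[[matrix.gene_row(g) for g in needed], :]

    engine = _Engine(X, subset_codes, age_codes, subsets)
    lig_rows, rec_rows, send_grp, recv_grp, meta = _record_index(
        pairs, rows, len(subsets)
    )

    M0 = engine.group_means(age_codes)
    S_obs = M0[lig_rows, send_grp] * M0[rec_rows, recv_grp]
    threshold = S_obs - _TIE_RTOL * (np.abs(S_obs) + 1e-300)

    N = config.n_permutations
    rng = np.random.default_rng(config.seed)
    n_ge = np.zeros(len(S_obs), dtype=int)
    for _ in range(N):
        Mp = engine.group_means(engine.permuted_ages(rng))
        S_p = Mp[lig_rows, send_grp] * Mp[rec_rows, recv_grp]
        n_ge += S_p >= threshold

    records = []
    for k, (pi, si, ri, ai) in enumerate(meta):
        n = int(n_ge[k])
        p = n / N
        records.append(
            InteractionRecord(
                ligand=pairs[pi][0],
                receptor=pairs[pi][1],
                sender=subsets[si],
                receiver=subsets[ri],
                age_group=AGE_GROUPS[ai],
                S=float(S_obs[k]),
                n=n,
                N=N,
                p=p,
                significant=p <= config.alpha_crosstalk,
                p_pseudo=(n + 1) / (N + 1) if config.crosstalk_pseudo else None,
            )
        )
    return CrosstalkResult(records, skipped)


def permutation_pvalue(
    matrix: ExpressionMatrix,
    annotation: CellAnnotation,
    pair: tuple[str, str],
    sender: str,
    receiver: str,
    age_group: str,
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[float, int, int, float]:
    """(S, n, N, p) for a single interaction.

    Same permutation scheme as :func:`run_crosstalk`: every subset's labels
    are shuffled each iteration, n counts permuted scores >= S (ties
    included), p = n/N.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    config = AnalysisConfig(n_permutations=n_permutations, seed=seed)
    table = LRPairTable.from_pairs([pair])
    result = run_crosstalk(matrix, annotation, table, config)
    if not result.records:
        lig, rec, reason = result.skipped_pairs[0]
        raise KeyError(f"pair {lig}->{rec} could not be scored: {reason}")
    rec = next(
        r
        for r in result.records
        if r.sender == sender and r.receiver == receiver and r.age_group == age_group
    )
    return rec.S, rec.n, rec.N, rec.p


def _check_alignment(matrix: ExpressionMatrix, annotation: CellAnnotation) -> None:
    if len(annotation) != matrix.n_cells or not np.array_equal(
        annotation.cell_ids, np.array(matrix.cell_ids, dtype=object)
    ):
        raise ValueError("annotation is not aligned with the matrix cells")
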
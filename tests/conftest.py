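import numpy as np
import pytest

from scxtalk import CellAnnotation, ExpressionMatrix


def make_annotation(subsets, ages, cell_ids=None) -> CellAnnotation:
    subsets = np.asarray(subsets, dtype=object)
    if cell_ids is None:
        cell_ids = np.array([f"c{i}" for i in range(len(subsets))], dtype=object)
    return CellAnnotation(np.asarray(cell_ids, dtype=object), subsets,
                          np.asarray(ages, dtype=object))


def make_matrix(values, gene_ids=None, cell_ids=None, layer="raw") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(values.shape[0])]
    if cell_ids is None:
        cell_ids = [f"c{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(values, gene_ids, cell_ids, layer)


@pytest.fixture
def toy_two_subset():
    """Two subsets, 2 young + 2 old cells each, integer counts, 4 genes.

    Small enough that every within-subset label arrangement (6 x 6 = 36)
    can be enumerated.
    """
    rng = np.random.default_rng(42)
    values = rng.integers(0, 20, size=(4, 8)).astype(float)
    matrix = make_matrix(values, gene_ids=["L1", "R1", "L2", "R2"])
    annotation = make_annotation(
        subsets=["A"] * 4 + ["B"] * 4,
        ages=["young", "young", "old", "old"] * 2,
        cell_ids=matrix.cell_ids,
    )
    return matrix, annotation
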
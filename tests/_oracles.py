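"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own vectorised code paths: the
permutation oracle enumerates every within-subset age-label arrangement and
recomputes scores with plain masked means; the Wilcoxon oracle enumerates
every labelling of the pooled sample.
"""

from itertools import combinations, product

import numpy as np


def _masked_mean(values, row, mask):
    sel = values[row][mask]
    return sel.mean() if sel.size else np.nan


def exhaustive_crosstalk_pvalue(
    values: np.ndarray,
    subset: np.ndarray,
    age: np.ndarray,
    gene_rows: dict,
    ligand: str,
    receptor: str,
    sender: str,
    receiver: str,
    age_group: str,
) -> float:
    """Exact permutation p by enumerating all within-subset arrangements.

    Ties count ('as or higher'), matching the implementation's one-sided
    definition.
    """
    subsets = list(dict.fromkeys(subset))
    per_subset = []
    for s in subsets:
        idx = np.flatnonzero(subset == s)
        n_old = int((age[idx] == "old").sum())
        per_subset.append([set(c) for c in combinations(idx.tolist(), n_old)])

    lrow, rrow = gene_rows[ligand], gene_rows[receptor]

    def score(age_vec):
        send_mask = (subset == sender) & (age_vec == age_group)
        recv_mask = (subset == receiver) & (age_vec == age_group)
        return _masked_mean(values, lrow, send_mask) * _masked_mean(values, rrow, recv_mask)

    s_obs = score(age)
    tol = 1e-9 * (abs(s_obs) + 1e-300)
    n_ge = 0
    total = 0
    for combo in product(*per_subset):
        old_positions = set().union(*combo) if combo else set()
        age_vec = np.array(
            ["old" if i in old_positions else "young" for i in range(len(subset))],
            dtype=object,
        )
        total += 1
        if score(age_vec) >= s_obs - tol:
            n_ge += 1
    return n_ge / total


def exact_wilcoxon_two_sided_p(a, b) -> float:
    """Exact two-sided rank-sum p by enumerating every labelling.

    Assumes no ties.  Uses the U statistic (number of (x in a, y in b) pairs
    with x > y); two-sided p = 2 * min(P(U <= u), P(U >= u)), clipped to 1.
    """
    a, b = list(a), list(b)
    pooled = a + b
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    na = len(a)
    u_obs = sum(x > y for x in a for y in b)
    us = []
    for idx in combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        us.append(sum(x > y for x in ga for y in gb))
    us = np.array(us)
    p_le = (us <= u_obs).mean()
    p_ge = (us >= u_obs).mean()
    return min(1.0, 2 * min(p_le, p_ge))
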
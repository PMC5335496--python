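import numpy as np
import pytest

from micronorm.core_io import CountTable, GroupDesign
from micronorm.simulate import make_synthetic_template, simulate_da_dataset


@pytest.fixture
def small_table() -> CountTable:
    """3 taxa x 2 samples with equal library sizes of 10."""
    return CountTable(["t1", "t2", "t3"], ["s1", "s2"],
                      np.array([[5, 0], [3, 2], [2, 8]]))


@pytest.fixture
def sparse_table() -> CountTable:
    """A realistically sparse 200-taxon, 20-sample synthetic table."""
    tpl = make_synthetic_template(200, 0.9, seed=11)
    ds = simulate_da_dataset(tpl, n_per_group=10, fold_change=1.0,
                             tp_fraction=0.0, N_L=2000, seed=12)
    return ds.table


@pytest.fixture
def two_group_design(sparse_table) -> GroupDesign:
    return GroupDesign(dict(sparse_table.sample_group))


def brute_force_ancom_w(table, design, pseudocount=0.001, alpha=0.05):
    """Independent ANCOM oracle: explicit all-pairs loop using scipy."""
    import scipy.stats as sps

    m = table.n_taxa
    mask1, mask2, _ = design.two_group_masks(table.sample_ids)
    L = np.log(table.counts + pseudocount)
    W = np.zeros(m, dtype=int)
    for i in range(m):
        ps = []
        for j in range(m):
            if j == i:
                continue
            ratio = L[i] - L[j]
            if np.ptp(ratio) == 0:
                ps.append(1.0)
                continue
            ps.append(sps.mannwhitneyu(ratio[mask1], ratio[mask2],
                                       alternative="two-sided",
                                       method="asymptotic").pvalue)
        q = brute_force_bh(np.array(ps))
        W[i] = int(np.sum(q <= alpha))
    return W


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Independent step-up BH: q_(i) = min_{j>=i} m p_(j)/j, clipped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    best = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        best = min(best, m * p[idx] / rank)
        q[idx] = min(best, 1.0)
    return q
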
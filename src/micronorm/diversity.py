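"""Beta-diversity machinery: distances, PCoA, PAM clustering, PERMANOVA.

The PERMANOVA here partitions the Gower-centered total sum of squares by
*type I sequential* sums of squares, so a library-size covariate entered
before the biological term absorbs depth artifacts first — the convention
used when asking whether sequencing depth, rather than biology, drives an
ordination.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform

from .core_io import CountTable, GroupDesign, PhyloTree
from .normalization import NormalizedTable

_BOUNDED_METRICS = {"braycurtis", "jaccard", "unweighted_unifrac", "weighted_unifrac"}


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    data: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.sample_ids)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.data, self.data.T, atol=1e-10):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.data) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(self.data < -1e-12):
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.sample_ids)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes, ordered by eigenvalue
    eigenvalues: np.ndarray    # all eigenvalues, descending (negatives kept)
    proportion_explained: np.ndarray  # over positive eigenvalues only


@dataclass
class PermanovaResult:
    table: pd.DataFrame  # term, df, SS, R2, pseudo_F, p
    residual_ss: float
    total_ss: float
    n_permutations: int

    @property
    def residual_r2(self) -> float:
        return self.residual_ss / self.total_ss if self.total_ss > 0 else 0.0


@dataclass
class ClusteringResult:
    labels: dict[str, int]
    medoids: list[str]
    cost: float
    accuracy: Optional[float] = None
    accuracy_with_penalty: Optional[float] = None


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _values_matrix(values: CountTable | NormalizedTable) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(values, CountTable):
        return values.counts.astype(float), list(values.taxon_ids), list(values.sample_ids)
    return np.asarray(values.values, dtype=float), list(values.taxon_ids), list(values.sample_ids)


def compute_distance(
    values: CountTable | NormalizedTable,
    metric: str,
    tree: Optional[PhyloTree] = None,
) -> DistanceMatrix:
    """Pairwise sample distances for the common ecological metrics.

    metric in {euclidean, braycurtis, jaccard, unweighted_unifrac,
    weighted_unifrac}.  Jaccard is binary (presence = value > 0); weighted
    UniFrac is the normalized variant bounded in [0, 1].  Non-Euclidean
    metrics reject negative values (clamped variance-stabilized output is
    fine, raw output is not).
    """
    mat, taxa, samples = _values_matrix(values)
    metric = metric.lower().replace("-", "_").replace(" ", "_")
    if metric == "bray_curtis":
        metric = "braycurtis"
    X = mat.T  # samples x taxa
    if metric != "euclidean" and np.any(X < 0):
        raise ValueError(
            f"{metric} requires non-negative values; variance-stabilized "
            "output must be clamped before use with non-Euclidean metrics"
        )
    if metric == "euclidean":
        d = squareform(pdist(X, metric="euclidean"))
    elif metric == "braycurtis":
        d = squareform(pdist(X, metric="braycurtis"))
    elif metric == "jaccard":
        d = squareform(pdist(X > 0, metric="jaccard"))
    elif metric in ("unweighted_unifrac", "weighted_unifrac"):
        if tree is None:
            raise ValueError("UniFrac metrics require a tree")
        d = _unifrac(X, taxa, tree, weighted=metric.startswith("weighted"))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    d = np.nan_to_num(d, nan=0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(samples, (d + d.T) / 2, metric)


def _unifrac(X: np.ndarray, taxa: list[str], tree: PhyloTree, weighted: bool) -> np.ndarray:
    """UniFrac via per-branch descendant sums on the rooted tree.

    Unweighted: fraction of shared branch length that is unique to one
    sample's presence set.  Weighted: normalized variant (branch-length
    weighted difference of relative abundances, scaled to [0, 1]).
    """
    t = tree.tree
    tip_names = set(n.name for n in t.tips())
    present = [x for x in taxa if (X[:, taxa.index(x)] > 0).any()]
    missing = [x for x in present if x not in tip_names]
    if missing:
        raise ValueError(f"tree lacks tips for taxa: {missing[:5]}")
    taxon_idx = {x: i for i, x in enumerate(taxa)}
    branches = []  # (length, abundance-vector over samples)
    n_samples = X.shape[0]
    totals = X.sum(axis=1)
    # post-order accumulation of per-sample descendant abundance
    node_ab: dict[int, np.ndarray] = {}
    for node in t.postorder(include_self=True):
        if node.is_tip():
            ab = (X[:, taxon_idx[node.name]].astype(float)
                  if node.name in taxon_idx else np.zeros(n_samples))
        else:
            ab = np.zeros(n_samples)
            for child in node.children:
                ab = ab + node_ab[id(child)]
        node_ab[id(node)] = ab
        if node.parent is not None and (node.length or 0) > 0:
            branches.append((float(node.length), ab))
    d = np.zeros((n_samples, n_samples))
    lengths = np.array([b[0] for b in branches])
    A = np.stack([b[1] for b in branches])  # branches x samples
    with np.errstate(divide="ignore", invalid="ignore"):
        P = A / totals[None, :]
    P = np.nan_to_num(P)
    for i in range(n_samples):
        for j in range(i + 1, n_samples):
            if weighted:
                num = np.sum(lengths * np.abs(P[:, i] - P[:, j]))
                den = np.sum(lengths * (P[:, i] + P[:, j]))
                d[i, j] = num / den if den > 0 else 0.0
            else:
                pi, pj = A[:, i] > 0, A[:, j] > 0
                union = np.sum(lengths * (pi | pj))
                shared = np.sum(lengths * (pi & pj))
                d[i, j] = 1 - shared / union if union > 0 else 0.0
    return d + d.T


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Principal coordinate analysis by Gower-centered eigendecomposition.

    Negative eigenvalues (non-Euclidean input) are reported, not corrected;
    coordinate axes are built from the positive eigenvalues only, ordered by
    decreasing eigenvalue.  On Euclidean input the embedding reproduces the
    distances exactly.
    """
    if not np.all(np.isfinite(dm.data)):
        raise ValueError("non-finite distances")
    B = _gower_center(dm.data)
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(1e-10 * abs(eigvals[0]), 1e-12) if eigvals.size else eigvals > 0
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])[None, :]
    pos_sum = eigvals[pos].sum()
    prop = eigvals[pos] / pos_sum if pos_sum > 0 else eigvals[pos]
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=dm.sample_ids, columns=cols),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# PERMANOVA (sequential SS)
# ---------------------------------------------------------------------------

def _design_columns(design: GroupDesign, sample_ids: Sequence[str],
                    terms: Optional[Sequence[str]]) -> list[tuple[str, np.ndarray]]:
    """Ordered (term, columns) pairs: covariates in stored order, group last."""
    out: list[tuple[str, np.ndarray]] = []
    cov = design.covariates
    if terms is None:
        terms = (list(cov.columns) if cov is not None else []) + ["group"]
    for term in terms:
        if term == "group":
            labels = design.labels_for(sample_ids)
            uniq = sorted(set(labels))
            cols = np.column_stack([(labels == u).astype(float) for u in uniq[1:]])
            out.append((term, cols))
        else:
            if cov is None or term not in cov.columns:
                raise ValueError(f"unknown PERMANOVA term {term!r}")
            vec = cov.loc[list(sample_ids), term].to_numpy(dtype=float)
            out.append((term, vec[:, None]))
    return out


def permanova_sequential(
    dm: DistanceMatrix,
    design: GroupDesign,
    terms: Optional[Sequence[str]] = None,
    n_perm: int = 999,
    seed: Optional[int] = None,
) -> PermanovaResult:
    """Distance-based multivariate ANOVA with type-I (sequential) SS.

    Terms are fitted in order; each term's SS is the increment in explained
    Gower-centered SS over the preceding terms, so R2 attribution depends on
    term order by design.  P-values come from permuting sample identities,
    with the (b+1)/(m+1) estimator so p is never exactly zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = dm.n
    G = _gower_center(dm.data)
    total_ss = np.trace(G)
    cols = _design_columns(design, dm.sample_ids, terms)
    # cumulative hat matrices
    hats, dfs, names = [], [], []
    X = np.ones((n, 1))
    prev_rank = 1
    for name, c in cols:
        const = np.all(c == c[0:1, :], axis=0)
        if const.all():
            import warnings as _w
            _w.warn(f"constant covariate {name!r}: R2 = 0")
        X = np.column_stack([X, c])
        Q, R = np.linalg.qr(X)
        rank = int(np.sum(np.abs(np.diag(R)) > 1e-10))
        Qr = Q[:, :rank]
        hats.append(Qr @ Qr.T)
        dfs.append(rank - prev_rank)
        names.append(name)
        prev_rank = rank
    df_res = n - prev_rank

    def seq_stats(Gm: np.ndarray) -> tuple[np.ndarray, float]:
        explained = np.array([np.sum(H * Gm) for H in hats])
        ss = np.diff(np.concatenate([[0.0], explained]))
        resid = np.trace(Gm) - explained[-1]
        return ss, resid

    ss_obs, resid_obs = seq_stats(G)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_obs = (ss_obs / np.maximum(dfs, 1)) / (resid_obs / max(df_res, 1))
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(hats))
    for _ in range(n_perm):
        idx = rng.permutation(n)
        Gp = G[np.ix_(idx, idx)]
        ss_p, resid_p = seq_stats(Gp)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_p = (ss_p / np.maximum(dfs, 1)) / (resid_p / max(df_res, 1))
        exceed += f_p >= f_obs - 1e-12
    pvals = (exceed + 1) / (n_perm + 1)
    r2 = ss_obs / total_ss if total_ss > 0 else np.zeros_like(ss_obs)
    tbl = pd.DataFrame({
        "term": names, "df": dfs, "SS": ss_obs, "R2": r2,
        "pseudo_F": f_obs, "p": pvals,
    })
    return PermanovaResult(tbl, residual_ss=float(resid_obs),
                           total_ss=float(total_ss), n_permutations=n_perm)


# ---------------------------------------------------------------------------
# PAM clustering
# ---------------------------------------------------------------------------

def _pam_cost(d: np.ndarray, medoids: list[int]) -> tuple[float, np.ndarray]:
    sub = d[:, medoids]
    assign = np.argmin(sub, axis=1)
    return float(sub[np.arange(d.shape[0]), assign].sum()), assign


def _pam_build(d: np.ndarray, k: int) -> list[int]:
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        best, best_cost = None, np.inf
        for cand in range(n):
            if cand in medoids:
                continue
            cost, _ = _pam_cost(d, medoids + [cand])
            if cost < best_cost:
                best, best_cost = cand, cost
        medoids.append(best)
    return medoids


def _pam_swap(d: np.ndarray, medoids: list[int]) -> tuple[list[int], float]:
    n = d.shape[0]
    medoids = list(medoids)
    cost, _ = _pam_cost(d, medoids)
    improved = True
    while improved:
        improved = False
        for mi in range(len(medoids)):
            for cand in range(n):
                if cand in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = cand
                c, _ = _pam_cost(d, trial)
                if c < cost - 1e-12:
                    medoids, cost, improved = trial, c, True
    return medoids, cost


def pam_cluster(
    dm: DistanceMatrix,
    k: int = 2,
    seed: Optional[int] = None,
    restarts: int = 10,
) -> ClusteringResult:
    """Partitioning around medoids: greedy BUILD then SWAP to a local optimum.

    The deterministic BUILD start is supplemented by seeded random restarts;
    the solution with the lowest total within-cluster distance wins.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > dm.n:
        raise ValueError("k exceeds number of samples")
    d = dm.data
    rng = np.random.default_rng(seed)
    best_medoids, best_cost = _pam_swap(d, _pam_build(d, k))
    for _ in range(max(0, restarts - 1)):
        init = list(rng.choice(dm.n, size=k, replace=False))
        medoids, cost = _pam_swap(d, init)
        if cost < best_cost - 1e-12:
            best_medoids, best_cost = medoids, cost
    _, assign = _pam_cost(d, best_medoids)
    labels = {s: int(a) for s, a in zip(dm.sample_ids, assign)}
    return ClusteringResult(
        labels=labels,
        medoids=[dm.sample_ids[m] for m in best_medoids],
        cost=best_cost,
    )


def clustering_accuracy(
    result: ClusteringResult,
    truth: GroupDesign,
    dropped: Sequence[str] = (),
    penalize_dropped: bool = False,
) -> float:
    """Fraction of samples assigned to the right cluster, maximized over
    cluster-label permutations (cluster indices are arbitrary).

    With ``penalize_dropped`` the denominator includes samples dropped before
    clustering (e.g. by rarefying), all counted as wrong — the convention
    that caps accuracy at (n - dropped)/n even for a perfect clustering.
    """
    if not result.labels:
        raise ValueError("empty clustering")
    sample_ids = list(result.labels)
    true_labels = truth.labels_for(sample_ids)
    pred = np.array([result.labels[s] for s in sample_ids])
    clusters = sorted(set(pred))
    groups = sorted(set(true_labels))
    contingency = np.zeros((len(clusters), len(groups)))
    for c, g in zip(pred, true_labels):
        contingency[clusters.index(c), groups.index(g)] += 1
    rows, cols = linear_sum_assignment(-contingency)
    correct = contingency[rows, cols].sum()
    denom = len(sample_ids) + (len(dropped) if penalize_dropped else 0)
    return float(correct / denom)
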
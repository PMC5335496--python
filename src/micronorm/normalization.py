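"""The seven count-table normalization methods compared by the toolkit.

Each method is a pure transform ``CountTable -> NormalizedTable`` that records
its per-sample scale factors and parameters.  Scaling methods (proportion,
logUQ, CSS, DESeq size factors, TMM) rescale by a global constant C = median
library size so all outputs live on a comparable "counts" scale.

Methods
-------
none        counts passed through unchanged
proportion  columns scaled by their sum (total-sum scaling)
rarefy      subsample each column to an even depth without replacement
            (multivariate hypergeometric); with-replacement is optional
logUQ       per-sample 75th percentile of nonzero counts as divisor, then log2
CSS         cumulative-sum scaling: divisor is the sum of each sample's counts
            up to an adaptively chosen quantile
DESeqVS     median-of-ratios size factors followed by a negative-binomial
            variance-stabilizing (glog) transform, negatives clamped to zero
TMM         trimmed mean of M-values against a reference sample
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core_io import CountTable

LOG2 = np.log(2.0)


@dataclass
class NormalizedTable:
    """Real-valued matrix produced by a normalization, plus its bookkeeping."""

    taxon_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    method: str
    scale_factors: Optional[np.ndarray] = None
    params: dict = field(default_factory=dict)
    sample_group: Optional[dict[str, str]] = None

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_count_table(self) -> CountTable:
        """Reinterpret integer-valued output (e.g. rarefied) as counts."""
        return CountTable(
            list(self.taxon_ids),
            list(self.sample_ids),
            np.round(self.values).astype(np.int64),
            sample_group=self.sample_group,
            provenance=f"normalized:{self.method}",
        )


def _median_library(table: CountTable) -> float:
    return float(np.median(table.library_sizes()))


def proportion_normalize(table: CountTable) -> NormalizedTable:
    """Total-sum scaling: each column divided by its library size."""
    depths = table.library_sizes().astype(float)
    if np.any(depths == 0):
        raise ValueError("all-zero sample cannot be proportion-normalized")
    values = table.counts / depths
    return NormalizedTable(
        list(table.taxon_ids), list(table.sample_ids), values,
        method="proportion", scale_factors=depths,
        sample_group=table.sample_group,
    )


def rarefy(
    table: CountTable,
    depth: int,
    with_replacement: bool = False,
    seed: Optional[int] = None,
) -> NormalizedTable:
    """Subsample every column to ``depth`` total counts.

    Without replacement each column is a multivariate-hypergeometric draw from
    its own counts; with replacement it is a multinomial draw on the column's
    proportions.  Samples shallower than ``depth`` are excluded and listed in
    ``params['dropped_samples']``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    depths = table.library_sizes()
    keep = depths >= depth
    if not keep.any():
        raise ValueError(f"no sample has library size >= {depth}")
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    kept_ids = [s for s, k in zip(table.sample_ids, keep) if k]
    cols = []
    for j, sid in enumerate(table.sample_ids):
        if not keep[j]:
            continue
        col = table.counts[:, j]
        if with_replacement:
            cols.append(rng.multinomial(depth, col / col.sum()))
        elif col.sum() == depth:
            cols.append(col.copy())
        else:
            cols.append(rng.multivariate_hypergeometric(col, depth))
    values = np.column_stack(cols).astype(np.int64)
    group = None
    if table.sample_group is not None:
        group = {s: g for s, g in table.sample_group.items() if s in kept_ids}
    return NormalizedTable(
        list(table.taxon_ids), kept_ids, values, method="rarefy",
        params={"depth": depth, "with_replacement": with_replacement,
                "seed": seed, "dropped_samples": dropped},
        sample_group=group,
    )


def loguq_normalize(table: CountTable, pseudocount: float = 1.0) -> NormalizedTable:
    """Log upper-quartile: scale by the 75th percentile of nonzero counts.

    The quantile is taken over each sample's *nonzero* counts; on ~90%-sparse
    tables the raw 75th percentile is 0, which would be degenerate.  Values are
    ``log2(count / s_j * C + pseudocount)`` with C the median library size.
    """
    C = _median_library(table)
    s = np.empty(table.n_samples)
    for j in range(table.n_samples):
        col = table.counts[:, j]
        nz = col[col > 0]
        if nz.size == 0:
            raise ValueError(f"sample {table.sample_ids[j]} has no nonzero counts")
        s[j] = np.quantile(nz, 0.75)
    scaled = table.counts / s[None, :] * C
    values = np.log2(scaled + pseudocount)
    return NormalizedTable(
        list(table.taxon_ids), list(table.sample_ids), values, method="logUQ",
        scale_factors=s,
        params={"pseudocount": pseudocount, "quantile": 0.75,
                "nonzero_only": True, "rescale_constant": C},
        sample_group=table.sample_group,
    )


def _css_choose_quantile(table: CountTable, grid: np.ndarray) -> Optional[float]:
    """Pick the smallest quantile where sample quantiles start diverging.

    Per-sample quantile curves (over nonzero counts) are compared to the
    across-sample median curve; the chosen point is the first grid value at
    which the median relative deviation exceeds its running minimum by more
    than 10%.  Returns None when no stable segment is found.
    """
    qmat = np.empty((table.n_samples, grid.size))
    for j in range(table.n_samples):
        nz = table.counts[:, j][table.counts[:, j] > 0]
        if nz.size < 2:
            return None
        qmat[j] = np.quantile(nz, grid)
    ref = np.median(qmat, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.median(np.abs(qmat - ref[None, :]), axis=0) / np.maximum(ref, 1e-12)
    lo = np.searchsorted(grid, 0.25)
    running_min = np.inf
    for i in range(lo, grid.size):
        running_min = min(running_min, max(rel[i], 1e-3))
        if rel[i] > 1.1 * running_min and rel[i] > rel[lo:i + 1].min():
            return float(grid[i])
    return None


def css_normalize(table: CountTable, quantile: float | str = "auto") -> NormalizedTable:
    """Cumulative-sum scaling: divisor is the sum of counts up to a quantile.

    With ``quantile='auto'`` the threshold is chosen adaptively from the
    segment of the count distributions that is invariant across samples;
    degenerate tables fall back to 0.5 with a warning.  ``quantile=1.0``
    reduces to proportion normalization up to the global constant.
    """
    if table.n_samples < 2:
        raise ValueError("CSS requires at least 2 samples")
    grid = np.arange(0.01, 1.0, 0.01)
    if quantile == "auto":
        chosen = _css_choose_quantile(table, grid)
        if chosen is None:
            warnings.warn("no stable CSS quantile found; falling back to 0.5")
            chosen = 0.5
    else:
        chosen = float(quantile)
        if not 0 < chosen <= 1:
            raise ValueError("quantile must be in (0, 1]")
    C = _median_library(table)
    s = np.empty(table.n_samples)
    for j in range(table.n_samples):
        col = table.counts[:, j]
        nz = col[col > 0]
        if nz.size == 0:
            raise ValueError(f"sample {table.sample_ids[j]} has no nonzero counts")
        thresh = np.quantile(nz, chosen)
        s[j] = col[col <= thresh].sum()
        if s[j] == 0:
            s[j] = col.sum()
    values = table.counts / s[None, :] * C
    return NormalizedTable(
        list(table.taxon_ids), list(table.sample_ids), values, method="CSS",
        scale_factors=s,
        params={"quantile": chosen, "rescale_constant": C},
        sample_group=table.sample_group,
    )


def deseq_size_factors(table: CountTable, pseudocount: Optional[float] = None) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Uses only taxa with strictly positive counts in every sample; if none
    exist (common in sparse tables) and ``pseudocount`` is given, all taxa are
    used after adding it.  A single-sample table gets factor 1.
    """
    counts = table.counts.astype(float)
    if table.n_samples == 1:
        return np.ones(1)
    if pseudocount is not None:
        counts = counts + pseudocount
        usable = np.ones(table.n_taxa, dtype=bool)
    else:
        usable = (counts > 0).all(axis=1)
        if not usable.any():
            raise ValueError(
                "no taxon is positive in all samples; pass a pseudocount"
            )
    sub = counts[usable]
    log_geo = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_geo[:, None]
    s = np.exp(np.median(ratios, axis=0))
    s /= np.exp(np.mean(np.log(s)))
    return s


def _glog(x: np.ndarray, alpha: float) -> np.ndarray:
    """NB variance-stabilizing transform, calibrated to the log2 asymptote.

    f(x) = log2((2*a*x + 1 + 2*sqrt(a*x*(1+a*x))) / (4*a)); for large x,
    f(4x) - f(x) -> 2, i.e. the transform behaves like log2.
    """
    ax = alpha * x
    return np.log2((2 * ax + 1 + 2 * np.sqrt(ax * (1 + ax))) / (4 * alpha))


def deseq_vs_normalize(
    table: CountTable,
    clamp_negatives: bool = True,
    pseudocount: Optional[float] = None,
) -> NormalizedTable:
    """Size-factor scaling plus a common-dispersion glog VST.

    A single NB dispersion is estimated by moments from the size-factor-scaled
    counts and drives a glog transform whose variance is approximately
    independent of the mean.  Negative outputs (low counts under high
    dispersion) are clamped to zero by default, the convention that makes the
    result usable with non-Euclidean ecological distances at the cost of
    erasing many rare taxa.
    """
    if table.n_samples < 2:
        raise ValueError("need >= 2 samples")
    try:
        s = deseq_size_factors(table, pseudocount=pseudocount)
    except ValueError:
        s = deseq_size_factors(table, pseudocount=1.0)
        pseudocount = 1.0
    q = table.counts / s[None, :]
    m = q.mean(axis=1)
    v = q.var(axis=1, ddof=1)
    ok = m > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (v[ok] - m[ok]) / m[ok] ** 2
    disp = disp[np.isfinite(disp) & (disp > 0)]
    if disp.size == 0:
        warnings.warn("no overdispersion detected; using Poisson-limit log transform")
        values = np.log2(q + 1)
        alpha = 0.0
    else:
        alpha = float(np.median(disp))
        values = _glog(q, alpha)
    clamped = False
    if clamp_negatives and np.any(values < 0):
        values = np.where(values < 0, 0.0, values)
        clamped = True
    return NormalizedTable(
        list(table.taxon_ids), list(table.sample_ids), values, method="DESeqVS",
        scale_factors=s,
        params={"dispersion": alpha, "clamp_negatives": clamp_negatives,
                "clamped": clamped, "pseudocount": pseudocount},
        sample_group=table.sample_group,
    )


def tmm_normalize(
    table: CountTable,
    trim_M: float = 0.30,
    trim_A: float = 0.05,
) -> NormalizedTable:
    """Trimmed mean of M-values scaling.

    For each sample a factor is computed as 2 to the precision-weighted mean
    of per-taxon log-ratios (M-values) against a reference sample, after
    trimming ``trim_M`` from each tail of the M distribution and ``trim_A``
    from each tail of the average-abundance distribution.  Factors are
    rescaled to geometric mean 1; effective library sizes are N_j * factor_j.
    """
    if table.n_samples < 2:
        raise ValueError("need >= 2 samples")
    counts = table.counts.astype(float)
    N = table.library_sizes().astype(float)
    uq = np.array([
        np.quantile(counts[:, j][counts[:, j] > 0], 0.75) / N[j]
        if (counts[:, j] > 0).any() else 0.0
        for j in range(table.n_samples)
    ])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(table.n_samples)
    kr = counts[:, ref]
    for j in range(table.n_samples):
        if j == ref:
            continue
        kj = counts[:, j]
        both = (kj > 0) & (kr > 0)
        if not both.any():
            warnings.warn(
                f"sample {table.sample_ids[j]} shares no taxon with reference; factor 1"
            )
            continue
        pj, pr = kj[both] / N[j], kr[both] / N[ref]
        M = np.log2(pj / pr)
        A = 0.5 * np.log2(pj * pr)
        n = M.size
        rank_M = np.argsort(np.argsort(M))
        rank_A = np.argsort(np.argsort(A))
        lo_M, hi_M = np.floor(n * trim_M), n - np.floor(n * trim_M)
        lo_A, hi_A = np.floor(n * trim_A), n - np.floor(n * trim_A)
        keep = (rank_M >= lo_M) & (rank_M < hi_M) & (rank_A >= lo_A) & (rank_A < hi_A)
        if not keep.any():
            keep = np.ones(n, dtype=bool)
        w = 1.0 / ((N[j] - kj[both]) / (N[j] * kj[both])
                   + (N[ref] - kr[both]) / (N[ref] * kr[both]))
        factors[j] = 2 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    C = _median_library(table)
    values = counts / (N * factors)[None, :] * C
    return NormalizedTable(
        list(table.taxon_ids), list(table.sample_ids), values, method="TMM",
        scale_factors=factors,
        params={"trim_M": trim_M, "trim_A": trim_A, "reference": table.sample_ids[ref],
                "rescale_constant": C},
        sample_group=table.sample_group,
    )


_METHODS = {"none", "proportion", "rarefy", "logUQ", "CSS", "DESeqVS", "TMM"}


def normalize(table: CountTable, method: str, **params) -> NormalizedTable:
    """Dispatch to the named normalization; ``none`` passes counts through."""
    if method == "none":
        return NormalizedTable(
            list(table.taxon_ids), list(table.sample_ids),
            table.counts.astype(float), method="none",
            sample_group=table.sample_group,
        )
    if method == "proportion":
        return proportion_normalize(table)
    if method == "rarefy":
        return rarefy(table, **params)
    if method == "logUQ":
        return loguq_normalize(table, **params)
    if method == "CSS":
        return css_normalize(table, **params)
    if method == "DESeqVS":
        return deseq_vs_normalize(table, **params)
    if method == "TMM":
        return tmm_normalize(table, **params)
    raise ValueError(f"unknown normalization method {method!r}; choose from {sorted(_METHODS)}")
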
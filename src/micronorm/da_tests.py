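"""Two-group differential-abundance tests for sparse count tables.

Implemented procedures: per-taxon Mann-Whitney and Welch t tests, ANCOM
(all-pairs log-ratio testing with the W count statistic), negative-binomial
GLM tests (Wald with optional log-fold-change shrinkage, and an exact
conditional mode), a voom-style precision-weighted moderated t, and
zero-inflated Gaussian / lognormal mixtures fitted by EM.  All tests return a
:class:`DATestResult` with per-taxon statistics, raw p, Benjamini-Hochberg q,
and the called set at a nominal FDR level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit, polygamma
from scipy.stats import nbinom, rankdata

from .core_io import CountTable, GroupDesign
from .normalization import NormalizedTable, css_normalize, deseq_size_factors, tmm_normalize

LOG2 = np.log(2.0)


@dataclass
class DATestResult:
    """Per-taxon test output: statistic, log2 fold change, p, BH q, calls."""

    table: pd.DataFrame
    method: str
    alpha: float
    params: dict = field(default_factory=dict)

    @property
    def called(self) -> set[str]:
        return set(self.table.index[self.table["called"]])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="taxon_id")


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values.

    NaN entries are excluded from the ranking and propagate as NaN.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    m = int(ok.sum())
    if m == 0:
        return q
    ps = p[ok]
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def _lfc_from_means(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """log2 ratio of group means for non-negative data, mean difference otherwise."""
    m1, m2 = v1.mean(axis=1), v2.mean(axis=1)
    if np.all(v1 >= 0) and np.all(v2 >= 0):
        return np.log2((m1 + 1e-9) / (m2 + 1e-9))
    return m1 - m2


def _finish(taxon_ids, stat, lfc, p, method, alpha, params) -> DATestResult:
    q = bh_adjust(np.asarray(p, dtype=float))
    called = np.where(np.isnan(q), False, q <= alpha)
    tbl = pd.DataFrame(
        {"statistic": stat, "lfc": lfc, "p": p, "q": q, "called": called},
        index=pd.Index(taxon_ids, name="taxon_id"),
    )
    return DATestResult(tbl, method=method, alpha=alpha, params=params)


def _split(values: np.ndarray, design: GroupDesign, sample_ids,
           min_per_group: int = 2) -> tuple[np.ndarray, np.ndarray, tuple[str, str]]:
    mask1, mask2, labels = design.two_group_masks(sample_ids)
    if mask1.sum() < min_per_group or mask2.sum() < min_per_group:
        raise ValueError(f"each group needs >= {min_per_group} samples")
    return values[:, mask1], values[:, mask2], labels


# ---------------------------------------------------------------------------
# rank / t tests
# ---------------------------------------------------------------------------

def mann_whitney_test(
    values: CountTable | NormalizedTable,
    design: GroupDesign,
    alpha: float = 0.05,
) -> DATestResult:
    """Two-sided Mann-Whitney U per taxon with mid-rank tie handling.

    Exact p when both groups have <= 8 samples and no ties; the normal
    approximation with tie correction otherwise.  A constant taxon gets p=1.
    """
    mat = values.counts.astype(float) if isinstance(values, CountTable) else values.values
    v1, v2, labels = _split(mat, design, values.sample_ids)
    small = v1.shape[1] <= 8 and v2.shape[1] <= 8
    m = mat.shape[0]
    stat = np.empty(m)
    p = np.empty(m)
    for i in range(m):
        a, b = v1[i], v2[i]
        if np.ptp(np.concatenate([a, b])) == 0:
            stat[i], p[i] = a.size * b.size / 2, 1.0
            continue
        method = "auto" if small else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        stat[i], p[i] = res.statistic, min(res.pvalue, 1.0)
    lfc = _lfc_from_means(v1, v2)
    return _finish(values.taxon_ids, stat, lfc, p, "mann_whitney", alpha,
                   {"groups": labels})


def welch_t_test(
    values: CountTable | NormalizedTable,
    design: GroupDesign,
    alpha: float = 0.05,
) -> DATestResult:
    """Two-sided Welch t with Satterthwaite degrees of freedom per taxon."""
    mat = values.counts.astype(float) if isinstance(values, CountTable) else values.values
    v1, v2, labels = _split(mat, design, values.sample_ids)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sps.ttest_ind(v1, v2, axis=1, equal_var=False)
    stat = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    zero_var = (v1.var(axis=1) == 0) & (v2.var(axis=1) == 0)
    equal_means = np.isclose(v1.mean(axis=1), v2.mean(axis=1))
    p[zero_var & equal_means] = 1.0
    stat[zero_var & equal_means] = 0.0
    p[zero_var & ~equal_means] = 0.0
    lfc = _lfc_from_means(v1, v2)
    return _finish(values.taxon_ids, stat, lfc, p, "welch_t", alpha,
                   {"groups": labels})


# ---------------------------------------------------------------------------
# ANCOM
# ---------------------------------------------------------------------------

def _mw_z_pvals(rows: np.ndarray, mask1: np.ndarray, mask2: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Mann-Whitney p (normal approximation, tie
    correction, continuity correction) for each row of ``rows``."""
    n1, n2 = int(mask1.sum()), int(mask2.sum())
    n = n1 + n2
    ranks = rankdata(rows, axis=1)
    U1 = ranks[:, mask1].sum(axis=1) - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    # tie correction: sum over tie groups of (t^3 - t) per row
    sorted_rows = np.sort(rows, axis=1)
    ties = np.zeros(rows.shape[0])
    for r in range(rows.shape[0]):
        _, counts = np.unique(sorted_rows[r], return_counts=True)
        ties[r] = np.sum(counts ** 3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - ties / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(U1 - mu) - 0.5) / np.sqrt(var)
    p = 2 * sps.norm.sf(z)
    p = np.where(var <= 0, 1.0, np.clip(p, 0.0, 1.0))
    return p


def ancom_test(
    table: CountTable,
    design: GroupDesign,
    pseudocount: float = 0.001,
    alpha: float = 0.05,
    w_mode: str = "threshold",
    w_threshold_frac: float = 0.7,
    bh_scope: str = "per_taxon",
    min_prevalence: float = 0.1,
) -> DATestResult:
    """Analysis of composition of microbiomes.

    For each ordered taxon pair (i, j) the per-sample additive log-ratio
    log((k_i + c)/(k_j + c)) is compared between groups with a Mann-Whitney
    test; each taxon's m-1 p-values are BH-adjusted (per-taxon scope by
    default, global optionally) and W_i counts the rejections.  The final
    call is W_i >= w_threshold_frac * (m-1) in ``threshold`` mode, or a
    largest-gap knee in the sorted W curve in ``empirical`` mode.

    Taxa detected in fewer than ``min_prevalence`` of samples (at least 2)
    are excluded from testing and from the log-ratio reference set, the
    standard preprocessing for this method: a ratio against an essentially
    never-observed taxon reduces to the taxon's own abundance over the
    pseudocount, which turns every global shift into a spurious rejection.
    Excluded taxa are reported with W = 0 and never called.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    m = table.n_taxa
    if m < 2:
        raise ValueError("ANCOM needs >= 2 taxa")
    mask1, mask2, labels = design.two_group_masks(table.sample_ids)
    n = table.n_samples
    min_det = max(2, int(np.ceil(min_prevalence * n)))
    keep = np.nonzero((table.counts > 0).sum(axis=1) >= min_det)[0]
    mf = keep.size
    if mf < 2:
        warnings.warn("fewer than 2 taxa pass the prevalence filter; no calls")
        keep = np.arange(m)
        mf = m
    L = np.log(table.counts[keep] + pseudocount)
    pmat = np.full((mf, mf), np.nan)
    for i in range(mf):
        ratios = L[i][None, :] - L  # rows j: log-ratio of taxon i vs j
        pmat[i, :] = _mw_z_pvals(ratios, mask1, mask2)
    np.fill_diagonal(pmat, np.nan)
    if bh_scope == "per_taxon":
        Wf = np.zeros(mf, dtype=int)
        for i in range(mf):
            q = bh_adjust(np.delete(pmat[i], i))
            Wf[i] = int(np.nansum(q <= alpha))
    elif bh_scope == "global":
        flat_q = bh_adjust(pmat.ravel()).reshape(mf, mf)
        Wf = np.nansum(flat_q <= alpha, axis=1).astype(int)
    else:
        raise ValueError("bh_scope must be 'per_taxon' or 'global'")
    if w_mode == "threshold":
        cutoff = w_threshold_frac * (mf - 1)
    elif w_mode == "empirical":
        cutoff = _w_knee_cutoff(Wf, mf)
    else:
        raise ValueError("w_mode must be 'threshold' or 'empirical'")
    W = np.zeros(m)
    W[keep] = Wf
    called = np.zeros(m, dtype=bool)
    called[keep] = Wf >= cutoff
    mat = table.counts.astype(float)
    v1, v2 = mat[:, mask1], mat[:, mask2]
    tbl = pd.DataFrame(
        {"statistic": W, "lfc": _lfc_from_means(v1, v2),
         "p": np.nan, "q": np.nan, "called": called},
        index=pd.Index(table.taxon_ids, name="taxon_id"),
    )
    return DATestResult(tbl, method="ancom", alpha=alpha,
                        params={"pseudocount": pseudocount, "w_mode": w_mode,
                                "w_threshold_frac": w_threshold_frac,
                                "bh_scope": bh_scope, "w_cutoff": float(cutoff),
                                "min_prevalence": min_prevalence,
                                "n_tested": int(mf),
                                "n_prevalence_filtered": int(m - mf),
                                "groups": labels})


def _w_knee_cutoff(W: np.ndarray, m: int) -> float:
    """Cutoff at the largest gap of the sorted-W curve within its upper 30%.

    An approximation to calling taxa from the empirical distribution of W;
    when no meaningful gap exists, nothing is called.
    """
    ws = np.sort(W)[::-1]
    top = max(2, int(np.ceil(0.3 * m)))
    seg = ws[:top]
    gaps = seg[:-1] - seg[1:]
    if gaps.size == 0 or gaps.max() <= 1:
        return m + 1  # no knee: call nothing
    k = int(np.argmax(gaps))
    return float(seg[k])


# ---------------------------------------------------------------------------
# negative-binomial GLM tests
# ---------------------------------------------------------------------------

def _nb_dispersions(counts: np.ndarray, s: np.ndarray, shrink: float = 0.5) -> np.ndarray:
    """Per-taxon NB dispersions by moments, shrunk toward a 1/mean trend.

    raw alpha_i = (var - mean)/mean^2 on size-factor-scaled counts; the trend
    alpha(m) = a0/m + a1 is fitted by non-negative least squares and the final
    estimate is the log-scale 50/50 (by default) blend of raw and trend.  The
    shrink weight is the knob separating conservative (DESeq-like, low
    shrink toward the trend keeps high raw estimates) from anticonservative
    (edgeR-like) dispersion behavior.
    """
    z = counts / s[None, :]
    m = z.mean(axis=1)
    v = z.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (v - m) / m ** 2
    raw = np.where(np.isfinite(raw), raw, np.nan)
    fit_ok = np.isfinite(raw) & (raw > 1e-6) & (m > 0)
    if fit_ok.sum() >= 2:
        from scipy.optimize import nnls
        X = np.column_stack([1.0 / m[fit_ok], np.ones(fit_ok.sum())])
        coef, _ = nnls(X, raw[fit_ok])
        a0, a1 = coef
    else:
        a0, a1 = 1.0, 0.1
    with np.errstate(divide="ignore"):
        trend = np.where(m > 0, a0 / np.maximum(m, 1e-12) + a1, np.nan)
    trend = np.maximum(trend, 1e-8)
    raw_f = np.maximum(np.where(np.isfinite(raw), raw, trend), 1e-8)
    alpha = np.exp(shrink * np.log(trend) + (1 - shrink) * np.log(raw_f))
    return np.where(m > 0, alpha, np.nan)


def _nb_group_fit(counts: np.ndarray, s: np.ndarray, alpha: np.ndarray,
                  mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """MLE of the per-taxon group mean scale m_g (mu_ij = s_j * m_g) and the
    Fisher information of b_g = log m_g, vectorized across taxa."""
    k = counts[:, mask]
    sj = s[mask]
    m = np.maximum(k.sum(axis=1) / sj.sum(), 1e-10)
    a = alpha[:, None]
    for _ in range(50):
        mu = sj[None, :] * m[:, None]
        w = 1.0 / (1.0 + a * mu)
        m_new = (w * k).sum(axis=1) / np.maximum((w * sj[None, :]).sum(axis=1), 1e-300)
        m_new = np.maximum(m_new, 1e-10)
        if np.nanmax(np.abs(np.log(m_new) - np.log(m))) < 1e-10:
            m = m_new
            break
        m = m_new
    mu = sj[None, :] * m[:, None]
    info = (mu / (1.0 + a * mu)).sum(axis=1)
    return m, info


def nb_glm_test(
    table: CountTable,
    design: GroupDesign,
    mode: str = "wald",
    shrink_lfc: bool = True,
    size_factors: Optional[np.ndarray] = None,
    alpha: float = 0.05,
    dispersion_shrink: float = 0.5,
) -> DATestResult:
    """Negative-binomial GLM tests for a two-group design.

    ``mode='wald'``: per-taxon NB GLM with a group covariate and log size
    factor offsets; the log-fold change is optionally shrunk toward zero with
    a zero-centered normal prior whose variance is estimated from the spread
    of the unshrunk estimates, then tested with a Wald z.

    ``mode='exact'``: conditional test on the split of the (size-factor
    equalized) group sums given their total, under NB with the fitted
    dispersion — the classic exact-test construction.

    All-zero taxa get p = NaN and are excluded from the BH ranking.
    """
    mask1, mask2, labels = design.two_group_masks(table.sample_ids)
    if mask1.sum() < 2 or mask2.sum() < 2:
        raise ValueError("each group needs >= 2 samples")
    counts = table.counts.astype(float)
    if size_factors is None:
        try:
            s = deseq_size_factors(table)
        except ValueError:
            s = deseq_size_factors(table, pseudocount=1.0)
    else:
        s = np.asarray(size_factors, dtype=float)
    disp = _nb_dispersions(counts, s, shrink=dispersion_shrink)
    disp_f = np.where(np.isfinite(disp), disp, 1e-8)
    m1, info1 = _nb_group_fit(counts, s, disp_f, mask1)
    m2, info2 = _nb_group_fit(counts, s, disp_f, mask2)
    lfc = (np.log(m1) - np.log(m2)) / LOG2
    se = np.sqrt(1.0 / np.maximum(info1, 1e-300) + 1.0 / np.maximum(info2, 1e-300)) / LOG2
    zero_taxa = counts.sum(axis=1) == 0
    params = {"mode": mode, "shrink_lfc": shrink_lfc, "groups": labels,
              "dispersion_shrink": dispersion_shrink}
    if mode == "wald":
        if shrink_lfc:
            ok = np.isfinite(lfc) & np.isfinite(se) & ~zero_taxa
            prior_var = max(np.var(lfc[ok]) - np.median(se[ok] ** 2), 1e-6) if ok.any() else 1.0
            shrinkage = prior_var / (prior_var + se ** 2)
            lfc_out = lfc * shrinkage
            se_out = se * np.sqrt(shrinkage)
            params["lfc_prior_var"] = float(prior_var)
        else:
            lfc_out, se_out = lfc, se
        with np.errstate(divide="ignore", invalid="ignore"):
            z = lfc_out / se_out
        p = 2 * sps.norm.sf(np.abs(z))
        p[zero_taxa] = np.nan
        z[zero_taxa] = np.nan
        return _finish(table.taxon_ids, z, lfc_out, p, "nb_glm_wald", alpha, params)
    elif mode == "exact":
        y = np.round(counts / s[None, :])
        S1 = np.round(y[:, mask1].sum(axis=1)).astype(np.int64)
        S2 = np.round(y[:, mask2].sum(axis=1)).astype(np.int64)
        p = np.array([
            _nb_exact_p(S1[i], S2[i], int(mask1.sum()), int(mask2.sum()), disp_f[i])
            for i in range(table.n_taxa)
        ])
        p[zero_taxa] = np.nan
        stat = S1.astype(float)
        return _finish(table.taxon_ids, stat, lfc, p, "nb_glm_exact", alpha, params)
    raise ValueError("mode must be 'wald' or 'exact'")


def _nb_exact_p(S1: int, S2: int, n1: int, n2: int, alpha_i: float,
                max_enumerate: int = 4000) -> float:
    """Two-sided conditional p for the split (S1, S2) of group sums.

    The sum of a group's NB counts is NB with size n_g / alpha; conditionally
    on the total, the probability of each split is enumerated (or normal-
    approximated for large totals) and the two-sided p sums all splits no
    more probable than the observed one.
    """
    T = S1 + S2
    if T == 0:
        return 1.0
    a = max(alpha_i, 1e-8)
    mu = T / (n1 + n2)
    R1, R2 = n1 / a, n2 / a
    M1, M2 = n1 * mu, n2 * mu
    p1, p2 = R1 / (R1 + M1), R2 / (R2 + M2)
    if T <= max_enumerate:
        ss = np.arange(T + 1)
        logp = nbinom.logpmf(ss, R1, p1) + nbinom.logpmf(T - ss, R2, p2)
        logp -= logp.max()
        prob = np.exp(logp)
        prob /= prob.sum()
        pobs = prob[S1]
        return float(min(1.0, prob[prob <= pobs * (1 + 1e-12)].sum()))
    V1 = M1 + M1 ** 2 / R1
    V2 = M2 + M2 ** 2 / R2
    mean_c = T * M1 / (M1 + M2)
    var_c = V1 * V2 / (V1 + V2)
    z = (abs(S1 - mean_c) - 0.5) / np.sqrt(max(var_c, 1e-12))
    return float(min(1.0, 2 * sps.norm.sf(z)))


# ---------------------------------------------------------------------------
# voom
# ---------------------------------------------------------------------------

def _trigamma_inverse(t: float) -> float:
    if t <= 0:
        return np.inf
    x = 0.5 + 1.0 / t
    for _ in range(50):
        tri = polygamma(1, x)
        step = tri * (1 - tri / t) / polygamma(2, x)
        x = max(x + step, 1e-8)
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def _squeeze_var(s2: np.ndarray, df: float | np.ndarray,
                 prior_mask: Optional[np.ndarray] = None) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes variance moderation by moments on log sample variances.

    Fits a scaled inverse-chi-square prior (df0, s0^2) to the observed s^2 via
    the mean/variance of log s^2, then returns the posterior variances
    (df0*s0^2 + df*s^2)/(df0 + df), the prior df, and the prior scale.  ``df``
    may be per-taxon; ``prior_mask`` restricts the taxa used to estimate the
    prior (e.g. to adequately observed ones).
    """
    df_arr = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (df_arr > 0)
    fit = ok & (prior_mask if prior_mask is not None else True)
    if fit.sum() < 2:
        fit = ok
    if fit.sum() < 2:
        return s2, 0.0, float(np.nanmedian(s2))
    e = np.log(s2[fit]) - polygamma(0, df_arr[fit] / 2) + np.log(df_arr[fit] / 2)
    var_e = np.var(e, ddof=1) - float(np.mean(polygamma(1, df_arr[fit] / 2)))
    if var_e > 1e-12:
        df0 = 2 * _trigamma_inverse(float(var_e))
    else:
        df0 = np.inf
    if np.isfinite(df0):
        s0 = np.exp(np.mean(e) + polygamma(0, df0 / 2) - np.log(df0 / 2))
        post = (df0 * s0 + df_arr * s2) / (df0 + df_arr)
    else:
        s0 = np.exp(np.mean(e))
        post = np.full_like(s2, s0)
    return post, float(df0), float(s0)


def voom_test(
    table: CountTable,
    design: GroupDesign,
    alpha: float = 0.05,
) -> DATestResult:
    """Precision-weighted moderated t on log2 counts-per-million.

    Library sizes are scaled by TMM factors; a lowess curve of sqrt residual
    standard deviation against mean log2 count supplies per-observation
    precision weights (predicted sd to the -4), and the weighted group
    contrast is tested with an empirical-Bayes moderated t.
    """
    mask1, mask2, labels = design.two_group_masks(table.sample_ids)
    n1, n2 = int(mask1.sum()), int(mask2.sum())
    if n1 < 3 or n2 < 3:
        raise ValueError("voom needs >= 3 samples per group for the variance trend")
    from statsmodels.nonparametric.smoothers_lowess import lowess
    N = table.library_sizes().astype(float)
    factors = tmm_normalize(table).scale_factors
    eff = N * factors
    y = np.log2((table.counts + 0.5) / (eff + 1.0)[None, :] * 1e6)
    m = table.n_taxa
    nonzero = table.counts.sum(axis=1) > 0
    mu1 = y[:, mask1].mean(axis=1)
    mu2 = y[:, mask2].mean(axis=1)
    fitted = np.where(mask1[None, :], mu1[:, None], mu2[:, None])
    resid = y - fitted
    df = n1 + n2 - 2
    s2 = (resid ** 2).sum(axis=1) / df
    sd_quarter = np.sqrt(np.sqrt(s2))
    mean_log = y.mean(axis=1)
    ok = nonzero & np.isfinite(sd_quarter)
    if ok.sum() >= 10:
        lo = lowess(sd_quarter[ok], mean_log[ok], frac=0.5, return_sorted=True)
        xs, ys = lo[:, 0], np.maximum(lo[:, 1], 1e-3)
        pred = np.interp(fitted, xs, ys)
    else:  # too few taxa for a trend: flat weights
        pred = np.full_like(fitted, max(float(np.median(sd_quarter[ok])), 1e-3) if ok.any() else 1.0)
    w = pred ** -4
    sw1, sw2 = w[:, mask1].sum(axis=1), w[:, mask2].sum(axis=1)
    mw1 = (w[:, mask1] * y[:, mask1]).sum(axis=1) / sw1
    mw2 = (w[:, mask2] * y[:, mask2]).sum(axis=1) / sw2
    fit_w = np.where(mask1[None, :], mw1[:, None], mw2[:, None])
    s2w = (w * (y - fit_w) ** 2).sum(axis=1) / df
    s2post, df0, _ = _squeeze_var(np.where(nonzero, s2w, np.nan), df)
    lfc = mw1 - mw2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / np.sqrt(s2post * (1.0 / sw1 + 1.0 / sw2))
    df_total = df + (df0 if np.isfinite(df0) else 1e6)
    p = 2 * sps.t.sf(np.abs(t), df_total)
    p[~nonzero] = np.nan
    t = np.where(nonzero, t, np.nan)
    return _finish(table.taxon_ids, t, lfc, p, "voom", alpha,
                   {"prior_df": df0, "groups": labels})


# ---------------------------------------------------------------------------
# zero-inflated Gaussian / lognormal
# ---------------------------------------------------------------------------

def _fit_depth_logistic(targets: np.ndarray, trials: np.ndarray,
                        logN: np.ndarray, init: Optional[np.ndarray] = None,
                        max_newton: int = 50) -> np.ndarray:
    """Weighted logistic fit of per-sample zero-mass probability on log depth.

    ``targets[j]`` is the expected number of structural zeros in sample j,
    ``trials[j]`` the number of taxa.  Newton with step halving, warm-started
    from ``init``; the returned coefficients never have a lower binomial
    objective than the start, so an EM outer loop stays monotone.
    """
    x = np.column_stack([np.ones_like(logN), logN])
    if np.std(logN) < 1e-8:
        x = x[:, :1]

    def objective(b: np.ndarray) -> float:
        pi = np.clip(expit(x @ b), 1e-12, 1 - 1e-12)
        return float(np.sum(targets * np.log(pi) + (trials - targets) * np.log(1 - pi)))

    if init is not None:
        beta = np.asarray(init[: x.shape[1]], dtype=float).copy()
    else:
        beta = np.zeros(x.shape[1])
        frac = np.clip(targets.sum() / trials.sum(), 1e-6, 1 - 1e-6)
        beta[0] = np.log(frac / (1 - frac))
    obj = objective(beta)
    for _ in range(max_newton):
        pi = np.clip(expit(x @ beta), 1e-10, 1 - 1e-10)
        grad = x.T @ (targets - trials * pi)
        W = trials * pi * (1 - pi)
        H = x.T @ (x * W[:, None])
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(x.shape[1]), grad)
        except np.linalg.LinAlgError:
            break
        new_beta, new_obj = beta + step, objective(beta + step)
        halvings = 0
        while new_obj < obj and halvings < 30:
            step *= 0.5
            new_beta, new_obj = beta + step, objective(beta + step)
            halvings += 1
        if new_obj < obj:
            break
        converged = np.max(np.abs(step)) < 1e-10
        beta, obj = new_beta, new_obj
        if converged:
            break
    if x.shape[1] == 1:
        beta = np.array([beta[0], 0.0])
    return beta


def zig_test(
    table: CountTable,
    design: GroupDesign,
    mode: str = "zig",
    max_iter: int = 10,
    tol: float = 1e-6,
    alpha: float = 0.05,
    normalized: Optional[NormalizedTable] = None,
) -> DATestResult:
    """Zero-inflated Gaussian (or lognormal-feature) mixture test.

    Each entry of log2(count + 1) is modeled as a mixture of a point mass at
    zero and a Gaussian whose mean is a per-taxon regression on the group
    indicator plus a log CSS-scale covariate (so sequencing-depth effects on
    the observed values are absorbed by a fitted coefficient rather than
    attributed to the group).  The zero-mass probability is a logistic
    function of log library size, which is exactly why this model misbehaves
    when library size information has been destroyed (e.g. after rarefying).
    Fitted by EM; the group effect on the Gaussian component is tested with a
    moderated t (``mode='zig'``) or a Wald z with shrunk variance
    (``mode='zi_lognormal'``).
    """
    if mode not in ("zig", "zi_lognormal"):
        raise ValueError("mode must be 'zig' or 'zi_lognormal'")
    mask1, mask2, labels = design.two_group_masks(table.sample_ids)
    if normalized is None:
        try:
            s = css_normalize(table).scale_factors
        except ValueError:
            s = table.library_sizes().astype(float)
        y = np.log2(table.counts + 1.0)
    else:
        s = table.library_sizes().astype(float)
        y = np.log2(np.asarray(normalized.values) + 1.0)
    Z = table.counts == 0
    m, n = y.shape
    N = table.library_sizes().astype(float)
    logN = np.log(np.maximum(N, 1.0))
    depth_informative = bool(np.std(logN) > 1e-8)
    # per-taxon mean model: intercept + group + log2 scale covariate
    offset = np.log2(s / np.median(s))
    cols = [np.ones(n), mask1.astype(float)]
    if np.std(offset) > 1e-8:
        cols.append(offset)
    X = np.column_stack(cols)  # n x p
    p_dim = X.shape[1]
    beta = _fit_depth_logistic(Z.sum(axis=0).astype(float),
                               np.full(n, float(m)), logN)
    coef = np.zeros((m, p_dim))
    # zeros start fully assigned to the point mass: the Gaussian component is
    # initialized from detected cells only, which keeps the mixture away from
    # the degenerate mode where chance detections in one group masquerade as
    # a clean group effect
    resp = np.where(Z, 1.0, 0.0)
    W = 1.0 - resp
    var_g = np.full(m, np.nan)  # unscaled variance of the group coefficient
    prev_ll = -np.inf
    ll_trace: list[float] = []

    def wls() -> None:
        """Per-taxon weighted least squares of y on X with weights W."""
        nonlocal coef, var_g
        XtWX = np.einsum("ij,jk,jl->ikl", W, X, X)  # m x p x p
        XtWy = np.einsum("ij,ij,jk->ik", W, y, X)   # m x p
        XtWX += 1e-8 * np.eye(p_dim)[None, :, :]
        coef = np.linalg.solve(XtWX, XtWy[:, :, None])[:, :, 0]
        var_g = np.linalg.inv(XtWX)[:, 1, 1]

    wls()
    mu0 = coef @ X.T
    sw0 = np.maximum(W.sum(axis=1), 1e-10)
    sigma = np.sqrt(np.maximum((W * (y - mu0) ** 2).sum(axis=1) / sw0, 0.25))
    for it in range(max_iter):
        pi = np.clip(expit(beta[0] + beta[1] * logN), 1e-10, 1 - 1e-10)
        mu = coef @ X.T
        dens = sps.norm.pdf(y, loc=mu, scale=sigma[:, None])
        # E-step: responsibility of the zero point mass for zero counts
        with np.errstate(divide="ignore", invalid="ignore"):
            den = pi[None, :] + (1 - pi)[None, :] * dens
        resp = np.where(Z, pi[None, :] / np.maximum(den, 1e-300), 0.0)
        ll = float(np.sum(np.where(
            Z,
            np.log(np.maximum(pi[None, :] + (1 - pi)[None, :] * dens, 1e-300)),
            np.log(np.maximum((1 - pi)[None, :] * dens, 1e-300)),
        )))
        ll_trace.append(ll)
        # M-step: weighted regression and variance per taxon
        W = np.where(Z, 1.0 - resp, 1.0)
        wls()
        mu = coef @ X.T
        sw_all = np.maximum(W.sum(axis=1), 1e-10)
        # variance floored on the log2 scale: without a floor the Gaussian
        # collapses onto the zero spike and swallows the point mass
        sigma = np.sqrt(np.maximum((W * (y - mu) ** 2).sum(axis=1) / sw_all, 0.25))
        # M-step: logistic zero-mass model on per-sample expected zeros
        beta = _fit_depth_logistic(resp.sum(axis=0), np.full(n, float(m)), logN,
                                   init=beta)
        if it > 0 and abs(ll - prev_ll) < tol * (1 + abs(prev_ll)):
            prev_ll = ll
            break
        prev_ll = ll
    sw1 = np.maximum(W[:, mask1].sum(axis=1), 1e-10)
    sw2 = np.maximum(W[:, mask2].sum(axis=1), 1e-10)
    lfc = coef[:, 1]
    df_i = np.maximum(sw1 + sw2 - float(p_dim), 1.0)
    detected = (~Z).sum(axis=1)
    usable = (detected >= 2) & ((~Z)[:, mask1].any(axis=1) | (~Z)[:, mask2].any(axis=1))
    # prior fitted on adequately observed taxa so near-singleton taxa do not
    # drag the prior scale toward the degenerate-variance floor
    s2post, df0, _ = _squeeze_var(np.where(usable, sigma ** 2, np.nan), df_i,
                                  prior_mask=detected >= max(4, n // 5))
    se = np.sqrt(s2post * var_g)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
    if mode == "zig":
        df_total = df_i + (df0 if np.isfinite(df0) else 1e6)
        p = 2 * sps.t.sf(np.abs(t), df_total)
    else:
        p = 2 * sps.norm.sf(np.abs(t))
    p = np.where(usable, p, np.nan)
    t = np.where(usable, t, np.nan)
    return _finish(table.taxon_ids, t, lfc, p, mode, alpha,
                   {"em_iterations": len(ll_trace), "log_likelihood": ll_trace,
                    "zero_model": (float(beta[0]), float(beta[1])),
                    "depth_informative": depth_informative, "groups": labels})


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

_COUNT_TESTS = {"ancom", "nb_wald", "nb_exact", "voom", "zig", "zi_lognormal"}


def run_da(
    table: CountTable,
    design: GroupDesign,
    method: str,
    normalization: str = "none",
    norm_params: Optional[dict] = None,
    **test_params,
) -> DATestResult:
    """Apply a normalization then a differential-abundance test.

    Count-model tests (ANCOM, NB GLM, voom, ZIG) accept only ``none`` or
    ``rarefy`` normalization — they model counts and reject transformed or
    negative-valued input.  Rank and t tests run on any non-negative
    normalized values.  Running ZIG on rarefied data is permitted but flagged:
    its zero model keys on library size, which rarefying equalizes.
    """
    from .normalization import normalize
    norm_params = dict(norm_params or {})
    norm = normalize(table, normalization, **norm_params)
    if method in _COUNT_TESTS:
        if normalization not in ("none", "rarefy"):
            raise ValueError(
                f"{method} models counts; normalization {normalization!r} is not meaningful"
            )
        counts_in = table if normalization == "none" else norm.to_count_table()
        if method == "ancom":
            result = ancom_test(counts_in, design, **test_params)
        elif method == "nb_wald":
            result = nb_glm_test(counts_in, design, mode="wald", **test_params)
        elif method == "nb_exact":
            result = nb_glm_test(counts_in, design, mode="exact", **test_params)
        elif method == "voom":
            result = voom_test(counts_in, design, **test_params)
        else:
            result = zig_test(counts_in, design,
                              mode=("zig" if method == "zig" else "zi_lognormal"),
                              **test_params)
            if normalization == "rarefy":
                result.params["library_size_warning"] = (
                    "zero-inflation model fitted on rarefied data; the library-"
                    "size covariate is no longer informative"
                )
    elif method == "mann_whitney":
        result = mann_whitney_test(norm, design, **test_params)
    elif method == "welch_t":
        result = welch_t_test(norm, design, **test_params)
    else:
        raise ValueError(f"unknown test method {method!r}")
    result.params["normalization"] = normalization
    return result
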
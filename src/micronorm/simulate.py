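"""Synthetic community templates and benchmark dataset generators.

A :class:`TemplateCommunity` is an "ecosystem": a taxon proportion vector
plus a count distribution family (multinomial, Dirichlet-multinomial with a
scalar overdispersion, or per-taxon gamma-Poisson).  Templates can be fitted
from real tables by moments, or synthesized with the heavy-tailed abundance
profile and ~90% sparsity typical of 16S OTU tables.

Dataset generators cover four benchmark designs:

* ``simulate_clustering_dataset`` — two template communities mixed at a
  controllable effect size, for clustering-recovery evaluation;
* ``simulate_da_dataset`` — two-group differential abundance with a
  *balanced* true-positive construction (fold changes applied in both
  groups' ecosystems so the renormalizers match exactly, making differential
  abundance and differential relative abundance coincide), or the legacy
  one-sided post-sampling inflation;
* ``simulate_compositional_dataset`` — fold changes applied to ecosystem
  abundances of one group only, so every other taxon's relative abundance
  shifts too: the ground truth is the ecosystem-level set, and methods that
  test relative abundance inflate their false discovery rate;
* ``split_null`` — random or deliberately depth-uneven splits of a single
  biological group, where every call is a false positive.

Library sizes are drawn lognormally around the target median; all generators
are exactly reproducible from their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core_io import CountTable


@dataclass
class TemplateCommunity:
    """Ecosystem proportions plus a count-distribution family."""

    taxon_ids: list[str]
    proportions: np.ndarray
    family: str = "multinomial"  # multinomial | dirichlet_multinomial | gamma_poisson
    theta: Optional[float] = None          # DM overdispersion in (0, 1)
    gp_shape: Optional[np.ndarray] = None  # per-taxon gamma shape
    gp_rate: Optional[np.ndarray] = None   # per-taxon gamma rate (mean = shape/rate)
    source: str = ""

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if np.any(self.proportions < 0):
            raise ValueError("proportions must be non-negative")
        total = self.proportions.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"proportions sum to {total}, not 1")
        if self.family == "dirichlet_multinomial" and not (self.theta and self.theta > 0):
            raise ValueError("DM family requires theta > 0")
        if self.family == "gamma_poisson":
            if self.gp_shape is None or self.gp_rate is None:
                raise ValueError("GP family requires per-taxon shape and rate")
            if np.any(np.asarray(self.gp_shape) <= 0) or np.any(np.asarray(self.gp_rate) <= 0):
                raise ValueError("GP shape and rate must be positive")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)


@dataclass
class SimulationDesign:
    kind: str
    params: dict
    seed: Optional[int] = None


@dataclass
class SimulatedDataset:
    """A count table with recorded ground truth and design parameters."""

    table: CountTable
    truth: dict[str, tuple[str, float]]  # taxon -> (group with raised abundance, multiplier)
    design: SimulationDesign
    group_proportions: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def truth_set(self) -> set[str]:
        return set(self.truth)


# ---------------------------------------------------------------------------
# template fitting
# ---------------------------------------------------------------------------

def fit_multinomial(table: CountTable) -> TemplateCommunity:
    """Pooled proportions: row sums over the grand total."""
    if table.n_samples < 1:
        raise ValueError("empty table")
    totals = table.counts.sum(axis=1).astype(float)
    return TemplateCommunity(
        list(table.taxon_ids), totals / totals.sum(),
        family="multinomial", source=table.provenance,
    )


def fit_dirichlet_multinomial(table: CountTable) -> TemplateCommunity:
    """Method-of-moments Dirichlet-multinomial fit.

    pi-hat is the mean of sample proportions; the overdispersion theta
    (intraclass correlation, 0 = multinomial limit) comes from the
    across-sample variance of proportions: for each taxon
    Var(p_i) ~ pi(1-pi) (theta + (1-theta)/N), solved and averaged with
    pi(1-pi) weights.  The estimate is clipped away from the boundaries.
    """
    if table.n_samples < 2:
        raise ValueError("DM fit needs >= 2 samples")
    depths = table.library_sizes().astype(float)
    P = table.counts / depths[None, :]
    pi = P.mean(axis=1)
    v = P.var(axis=1, ddof=1)
    n_harm = 1.0 / np.mean(1.0 / depths)
    w = pi * (1 - pi)
    ok = w > 1e-12
    theta_i = (v[ok] / w[ok] - 1.0 / n_harm) / (1.0 - 1.0 / n_harm)
    theta = float(np.average(theta_i, weights=w[ok]))
    theta = float(np.clip(theta, 1e-8, 1 - 1e-8))
    return TemplateCommunity(
        list(table.taxon_ids), pi / pi.sum(),
        family="dirichlet_multinomial", theta=theta, source=table.provenance,
    )


def fit_gamma_poisson(table: CountTable) -> TemplateCommunity:
    """Per-taxon gamma-Poisson fit from means and variances.

    Counts are first scaled to a common reference depth (the median library
    size); for each taxon, shape = m^2/(v-m) and rate = m/(v-m) when the
    variance exceeds the mean, else the Poisson limit (very large shape)
    is used and flagged.
    """
    if table.n_samples < 2:
        raise ValueError("GP fit needs >= 2 samples")
    depths = table.library_sizes().astype(float)
    ref = float(np.median(depths))
    z = table.counts / depths[None, :] * ref
    m = z.mean(axis=1)
    v = z.var(axis=1, ddof=1)
    shape = np.empty(table.n_taxa)
    rate = np.empty(table.n_taxa)
    poisson_limit = v <= m
    excess = np.where(poisson_limit, np.nan, v - m)
    shape = np.where(poisson_limit, 1e6, m ** 2 / excess)
    rate = np.where(poisson_limit, 1e6 / np.maximum(m, 1e-12), m / excess)
    shape = np.maximum(np.nan_to_num(shape, nan=1e6), 1e-12)
    rate = np.maximum(np.nan_to_num(rate, nan=1e6), 1e-12)
    pi = m / m.sum()
    tpl = TemplateCommunity(
        list(table.taxon_ids), pi, family="gamma_poisson",
        gp_shape=shape, gp_rate=rate, source=table.provenance,
    )
    # mean at reference depth is shape/rate; proportions track it
    tpl.fitted_depth = ref  # type: ignore[attr-defined]
    tpl.poisson_limit = poisson_limit  # type: ignore[attr-defined]
    return tpl


def make_synthetic_template(
    n_taxa: int,
    sparsity_target: float = 0.9,
    seed: Optional[int] = None,
    reference_depth: int = 2000,
) -> TemplateCommunity:
    """Heavy-tailed synthetic ecosystem hitting a target zero fraction.

    The community has two blocks, mimicking the structure of real OTU
    tables: an observable block with lognormal abundances (sigma = 1.2, so
    the dominant taxon holds roughly 5-15% of reads rather than an
    unrealistic majority) carrying almost all of the mass, and a rare tail
    of near-detection-limit taxa carrying ~2.5%.  The observable fraction is
    tuned by bisection so that multinomial sampling at the reference depth
    yields approximately the target fraction of zero cells (computed
    analytically as mean_i exp(-N * pi_i)).  Deterministic given the seed.
    """
    if n_taxa < 10:
        raise ValueError("need >= 10 taxa")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n_taxa)
    marg_u = rng.uniform(size=n_taxa)
    tail_w = rng.uniform(0.2, 1.0, n_taxa)
    # marginal taxa straddle the detection limit; tail taxa sit far below it
    # (~0.01 expected reads each), as in real tables' long rare tail
    tail_pi_each = 0.01 / reference_depth

    def build(frac_obs: float) -> np.ndarray:
        n_obs = max(2, int(round(frac_obs * n_taxa)))
        n_marg = min(n_obs, n_taxa - n_obs)
        pi = np.empty(n_taxa)
        lo, hi = 0.05 / reference_depth, 5.0 / reference_depth
        pi[n_obs:n_obs + n_marg] = lo * (hi / lo) ** marg_u[n_obs:n_obs + n_marg]
        tail = tail_w[n_obs + n_marg:]
        pi[n_obs + n_marg:] = tail / tail.mean() * tail_pi_each if tail.size else tail
        rest_mass = pi[n_obs:].sum()
        obs = np.exp(1.2 * z[:n_obs])
        pi[:n_obs] = obs / obs.sum() * (1 - rest_mass)
        return pi

    def zero_frac(frac_obs: float) -> float:
        return float(np.mean(np.exp(-reference_depth * build(frac_obs))))

    # zero fraction decreases as the observable block grows
    lo, hi = 3.0 / n_taxa, 0.95
    f_lo, f_hi = zero_frac(lo), zero_frac(hi)
    if not f_hi <= sparsity_target <= f_lo:
        nearest = lo if abs(sparsity_target - f_lo) < abs(sparsity_target - f_hi) else hi
        warnings.warn(
            f"sparsity target {sparsity_target} unattainable with {n_taxa} taxa "
            f"at depth {reference_depth}; using nearest attainable {zero_frac(nearest):.3f}"
        )
        frac = nearest
    else:
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if zero_frac(mid) > sparsity_target:
                lo = mid
            else:
                hi = mid
        frac = 0.5 * (lo + hi)
    pi = build(frac)
    order = np.argsort(pi)[::-1]
    return TemplateCommunity(
        [f"OTU_{i}" for i in range(n_taxa)], pi[order],
        family="multinomial", source=f"synthetic(seed={seed},frac_obs={frac:.3f})",
    )


def make_template_pair(
    n_taxa: int,
    sparsity_target: float = 0.9,
    seed: Optional[int] = None,
) -> tuple[TemplateCommunity, TemplateCommunity]:
    """Two synthetic ecosystems over one taxon universe with disjoint
    dominant taxa (the second is a random permutation of the first), standing
    in for two distinct environments."""
    a = make_synthetic_template(n_taxa, sparsity_target, seed=seed)
    rng = np.random.default_rng(None if seed is None else seed + 1)
    perm = rng.permutation(n_taxa)
    b = TemplateCommunity(list(a.taxon_ids), a.proportions[perm],
                          family="multinomial", source=a.source + "+perm")
    return a, b


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------

def _draw_depths(rng: np.random.Generator, n: int, N_L: int, spread: float) -> np.ndarray:
    return np.maximum(1, np.round(N_L * np.exp(rng.normal(0.0, spread, size=n)))).astype(np.int64)


def _sample_counts(
    rng: np.random.Generator,
    pi: np.ndarray,
    depths: np.ndarray,
    family: str,
    theta: Optional[float] = None,
    gp_shape: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Draw a taxa x samples count block from one ecosystem vector."""
    m = pi.size
    cols = []
    if family == "multinomial":
        for N in depths:
            cols.append(rng.multinomial(int(N), pi))
    elif family == "dirichlet_multinomial":
        if theta is None or not 0 < theta < 1:
            raise ValueError("DM sampling needs theta in (0, 1)")
        conc = (1 - theta) / theta
        alpha = np.maximum(pi * conc, 1e-10)
        for N in depths:
            p = rng.dirichlet(alpha)
            cols.append(rng.multinomial(int(N), p))
    elif family == "gamma_poisson":
        if gp_shape is None:
            raise ValueError("GP sampling needs per-taxon shapes")
        shape = np.broadcast_to(np.asarray(gp_shape, dtype=float), (m,))
        for N in depths:
            lam = np.where(
                pi > 0,
                rng.gamma(shape, np.divide(pi, shape, out=np.zeros(m), where=shape > 0)),
                0.0,
            )
            cols.append(rng.poisson(lam * int(N)))
    else:
        raise ValueError(f"unknown family {family!r}")
    return np.column_stack(cols).astype(np.int64)


def _stratified_tp_choice(rng: np.random.Generator, pi: np.ndarray, n_tp: int,
                          N_L: Optional[int] = None) -> np.ndarray:
    """Pick true-positive taxa stratified by abundance quartile, so rare and
    common taxa are both represented.

    Candidates are restricted to taxa observable at the target depth
    (expected count >= 1, i.e. pi >= 1/N_L): a taxon that is essentially
    never sequenced cannot carry a detectable signal, and real benchmark
    designs inflate observed taxa.  If too few taxa qualify, the most
    abundant 2*n_tp taxa become the pool.
    """
    if N_L is not None:
        eligible = np.nonzero(pi >= 1.0 / N_L)[0]
        if eligible.size < 2 * n_tp:
            eligible = np.argsort(pi)[::-1][: min(pi.size, 2 * n_tp)]
    else:
        eligible = np.arange(pi.size)
    order = eligible[np.argsort(pi[eligible])]
    strata = np.array_split(order, 4)
    picks: list[int] = []
    base, extra = divmod(n_tp, 4)
    for s, stratum in enumerate(strata):
        k = min(base + (1 if s < extra else 0), stratum.size)
        picks.extend(rng.choice(stratum, size=k, replace=False))
    # top up from the eligible pool if strata were too small
    remaining = [i for i in order if i not in set(picks)]
    rng.shuffle(remaining)
    picks.extend(remaining[: n_tp - len(picks)])
    return np.array(sorted(picks[:n_tp]))


def _mass_representative_tp_choice(rng: np.random.Generator, pi: np.ndarray,
                                   n_tp: int, tp_fraction: float,
                                   N_L: int) -> np.ndarray:
    """Pick ``n_tp`` taxa whose total abundance is close to ``tp_fraction``.

    Raising "x% of taxa" should also raise roughly x% of the community's
    mass — what a random draw from a real table achieves on average.  The
    selection walks observable taxa in random order, accepting while the
    mass budget allows, then pads the count with rare-tail taxa.
    """
    observable = np.nonzero(pi >= 1.0 / N_L)[0]
    order = rng.permutation(observable)
    picks: list[int] = []
    mass = 0.0
    for i in order:
        if len(picks) >= n_tp:
            break
        if mass + pi[i] > 1.2 * tp_fraction:
            continue
        picks.append(int(i))
        mass += pi[i]
        if mass >= tp_fraction:
            break
    tail = [int(i) for i in rng.permutation(pi.size)
            if i not in set(picks) and pi[i] < 1.0 / N_L]
    picks.extend(tail[: n_tp - len(picks)])
    return np.array(sorted(picks[:n_tp]))


def _build_table(
    counts1: np.ndarray, counts2: np.ndarray, taxon_ids: list[str], provenance: str,
) -> CountTable:
    n1, n2 = counts1.shape[1], counts2.shape[1]
    sample_ids = [f"g1_s{j}" for j in range(n1)] + [f"g2_s{j}" for j in range(n2)]
    groups = {s: ("group_1" if s.startswith("g1") else "group_2") for s in sample_ids}
    return CountTable(
        taxon_ids, sample_ids, np.column_stack([counts1, counts2]),
        sample_group=groups, provenance=provenance,
    )


# ---------------------------------------------------------------------------
# dataset generators
# ---------------------------------------------------------------------------

def simulate_clustering_dataset(
    template_A: TemplateCommunity,
    template_B: TemplateCommunity,
    effect_size: float,
    n_samples: int = 40,
    N_L: int = 2000,
    spread: float = 0.5,
    seed: Optional[int] = None,
) -> SimulatedDataset:
    """Mix two template ecosystems at a given effect size and sample counts.

    Class 1 draws from normalize(ES*pi_A + pi_B), class 2 from the mirror
    image; ES = 1 makes the classes identical (chance-level clustering) and
    large ES recovers the pure templates.  Library sizes are lognormal around
    N_L; counts are multinomial.
    """
    if effect_size < 1:
        raise ValueError("effect size must be >= 1")
    if template_A.taxon_ids != template_B.taxon_ids:
        union = sorted(set(template_A.taxon_ids) | set(template_B.taxon_ids))
        def pad(t: TemplateCommunity) -> np.ndarray:
            idx = {x: i for i, x in enumerate(t.taxon_ids)}
            out = np.zeros(len(union))
            for x, i in idx.items():
                out[union.index(x)] = t.proportions[i]
            return out
        pa, pb, taxa = pad(template_A), pad(template_B), union
    else:
        pa, pb, taxa = template_A.proportions, template_B.proportions, list(template_A.taxon_ids)
    mix1 = effect_size * pa + pb
    mix2 = effect_size * pb + pa
    pi1, pi2 = mix1 / mix1.sum(), mix2 / mix2.sum()
    rng = np.random.default_rng(seed)
    n1 = n_samples // 2
    n2 = n_samples - n1
    d1 = _draw_depths(rng, n1, N_L, spread)
    d2 = _draw_depths(rng, n2, N_L, spread)
    c1 = _sample_counts(rng, pi1, d1, "multinomial")
    c2 = _sample_counts(rng, pi2, d2, "multinomial")
    design = SimulationDesign(
        "clustering",
        {"effect_size": effect_size, "n_samples": n_samples, "N_L": N_L, "spread": spread},
        seed,
    )
    table = _build_table(c1, c2, taxa, f"clustering(ES={effect_size},seed={seed})")
    return SimulatedDataset(table, {}, design,
                            {"group_1": pi1, "group_2": pi2})


def simulate_da_dataset(
    template: TemplateCommunity,
    family: str = "multinomial",
    n_per_group: int = 25,
    fold_change: float = 5.0,
    tp_fraction: float = 0.1,
    design: str = "balanced",
    N_L: int = 2000,
    spread: float = 0.5,
    seed: Optional[int] = None,
    theta: Optional[float] = None,
    gp_shape: Optional[float | np.ndarray] = None,
) -> SimulatedDataset:
    """Two-group differential-abundance benchmark dataset.

    ``design='balanced'``: the true-positive set is split into two halves;
    one half is raised ``fold_change``-fold in group 1's ecosystem and the
    other half in group 2's, with the second half's multiplier adjusted so
    both renormalizers match exactly.  Consequently the taxa whose ecosystem
    proportions differ between groups are exactly the recorded truth set —
    differential abundance and differential relative abundance coincide.

    ``design='original'``: both groups draw from the same ecosystem and the
    truth taxa are inflated in group 1 *after* sampling, the legacy scheme
    whose renormalization artifact makes every taxon differentially
    relatively abundant.
    """
    if fold_change < 1:
        raise ValueError("fold change must be >= 1")
    pi = template.proportions
    m = pi.size
    theta = theta if theta is not None else template.theta
    shapes = gp_shape if gp_shape is not None else template.gp_shape
    if shapes is not None and np.isscalar(shapes):
        shapes = np.full(m, float(shapes))
    rng = np.random.default_rng(seed)
    n_tp = int(round(tp_fraction * m))
    if fold_change == 1.0 or n_tp == 0:
        truth: dict[str, tuple[str, float]] = {}
        pi1 = pi2 = pi
    elif design == "balanced":
        if tp_fraction >= 0.5:
            raise ValueError("balanced design requires tp_fraction < 0.5")
        if n_tp < 2:
            raise ValueError("balanced design needs >= 2 true positives (pairs)")
        tp = _stratified_tp_choice(rng, pi, n_tp, N_L=N_L)
        order = tp[np.argsort(pi[tp])[::-1]]
        half1, half2 = order[0::2], order[1::2]
        mass1, mass2 = pi[half1].sum(), pi[half2].sum()
        fc2 = 1.0 + (fold_change - 1.0) * mass1 / mass2 if mass2 > 0 else fold_change
        a1, a2 = pi.copy(), pi.copy()
        a1[half1] *= fold_change
        a2[half2] *= fc2
        S = a1.sum()  # == a2.sum() by construction
        pi1, pi2 = a1 / S, a2 / S
        truth = {template.taxon_ids[i]: ("group_1", fold_change) for i in half1}
        truth.update({template.taxon_ids[i]: ("group_2", fc2) for i in half2})
    elif design == "original":
        tp = _stratified_tp_choice(rng, pi, n_tp, N_L=N_L)
        truth = {template.taxon_ids[i]: ("group_1", fold_change) for i in tp}
        pi1 = pi2 = pi
    else:
        raise ValueError("design must be 'balanced' or 'original'")
    d1 = _draw_depths(rng, n_per_group, N_L, spread)
    d2 = _draw_depths(rng, n_per_group, N_L, spread)
    c1 = _sample_counts(rng, pi1, d1, family, theta=theta, gp_shape=shapes)
    c2 = _sample_counts(rng, pi2, d2, family, theta=theta, gp_shape=shapes)
    if design == "original" and truth:
        idx = [template.taxon_ids.index(t) for t in truth]
        c1[idx, :] = np.round(c1[idx, :] * fold_change).astype(np.int64)
    sim_design = SimulationDesign(
        "balanced_da" if design == "balanced" else "original_da",
        {"family": family, "n_per_group": n_per_group, "fold_change": fold_change,
         "tp_fraction": tp_fraction, "N_L": N_L, "spread": spread,
         "theta": theta, "design": design},
        seed,
    )
    table = _build_table(c1, c2, list(template.taxon_ids),
                         f"da({design},{family},FC={fold_change},seed={seed})")
    return SimulatedDataset(table, truth, sim_design,
                            {"group_1": pi1, "group_2": pi2})


def simulate_compositional_dataset(
    template: TemplateCommunity,
    fold_change: float,
    tp_fraction: float = 0.10,
    n_per_group: int = 25,
    N_L: int = 2000,
    spread: float = 0.5,
    seed: Optional[int] = None,
) -> SimulatedDataset:
    """Ecosystem-level inflation in one group only (compositional design).

    True-positive taxa are raised ``fold_change``-fold in group 1's
    *abundances*; both groups' proportion vectors are then renormalized, so
    every non-truth taxon's relative abundance strictly decreases in group 1.
    The recorded truth is the ecosystem-level set — false discovery measured
    against it captures the compositional artifact of relative-abundance
    tests.
    """
    if fold_change <= 1:
        raise ValueError("fold change must be > 1")
    if not 0 < tp_fraction <= 0.5:
        raise ValueError("tp_fraction must be in (0, 0.5]")
    pi = template.proportions
    m = pi.size
    rng = np.random.default_rng(seed)
    n_tp = max(1, int(round(tp_fraction * m)))
    tp = _mass_representative_tp_choice(rng, pi, n_tp, tp_fraction, N_L)
    a1 = pi.copy()
    a1[tp] *= fold_change
    pi1 = a1 / a1.sum()
    pi2 = pi
    d1 = _draw_depths(rng, n_per_group, N_L, spread)
    d2 = _draw_depths(rng, n_per_group, N_L, spread)
    c1 = _sample_counts(rng, pi1, d1, "multinomial")
    c2 = _sample_counts(rng, pi2, d2, "multinomial")
    truth = {template.taxon_ids[i]: ("group_1", fold_change) for i in tp}
    design = SimulationDesign(
        "compositional_da",
        {"fold_change": fold_change, "tp_fraction": tp_fraction,
         "n_per_group": n_per_group, "N_L": N_L, "spread": spread},
        seed,
    )
    table = _build_table(c1, c2, list(template.taxon_ids),
                         f"compositional(FC={fold_change},seed={seed})")
    return SimulatedDataset(table, truth, design, {"group_1": pi1, "group_2": pi2})


def split_null(
    table: CountTable,
    n_per_group: int,
    mode: str = "random",
    target_ratio: float = 10.0,
    seed: Optional[int] = None,
) -> SimulatedDataset:
    """Split one biological group into two pseudo-groups (empty truth).

    ``mode='random'`` splits uniformly; ``mode='uneven'`` picks the
    ``n_per_group`` deepest samples as one group and slides a window over the
    depth-sorted remainder to get mean library sizes differing by
    approximately ``target_ratio``.
    """
    if table.n_samples < 2 * n_per_group:
        raise ValueError("not enough samples to split")
    rng = np.random.default_rng(seed)
    depths = table.library_sizes().astype(float)
    if mode == "random":
        idx = rng.permutation(table.n_samples)[: 2 * n_per_group]
        g1, g2 = idx[:n_per_group], idx[n_per_group:]
    elif mode == "uneven":
        order = np.argsort(depths)[::-1]
        g1 = order[:n_per_group]  # deepest
        rest = order[n_per_group:]
        best, best_err = rest[-n_per_group:], np.inf
        mean_hi = depths[g1].mean()
        for start in range(rest.size - n_per_group + 1):
            window = rest[start:start + n_per_group]
            ratio = mean_hi / depths[window].mean()
            err = abs(ratio - target_ratio)
            if err < best_err:
                best, best_err = window, err
        g2 = best
        achieved = mean_hi / depths[g2].mean()
        if abs(achieved - target_ratio) / target_ratio > 0.2:
            warnings.warn(
                f"target depth ratio {target_ratio} unattainable; achieved {achieved:.2f}"
            )
    else:
        raise ValueError("mode must be 'random' or 'uneven'")
    ids1 = [table.sample_ids[i] for i in g1]
    ids2 = [table.sample_ids[i] for i in g2]
    sub = table.select_samples(ids1 + ids2)
    sub.sample_group = {s: ("group_1" if s in set(ids1) else "group_2")
                        for s in sub.sample_ids}
    design = SimulationDesign(
        "null_split",
        {"n_per_group": n_per_group, "mode": mode, "target_ratio": target_ratio},
        seed,
    )
    return SimulatedDataset(sub, {}, design, {})
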
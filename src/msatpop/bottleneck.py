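"""Bottleneck detection: heterozygosity excess and the M-ratio.

Two complementary signatures of a recent decline in effective population
size are implemented:

* **Heterozygosity excess.**  Shortly after a bottleneck, rare alleles are
  lost faster than gene diversity decays, so the observed gene diversity of a
  locus exceeds the mutation-drift-equilibrium expectation *given its
  observed allele count k*.  The equilibrium distribution of ``H_eq | k`` is
  obtained by coalescent simulation under a two-phase mutation model (TPM):
  genealogies of the sampled gene copies receive mutations one at a time at
  uniformly chosen points until exactly ``k`` distinct allelic states exist.
  Per-locus standardized differences are combined across loci with a
  one-tailed Wilcoxon signed-rank test for a positive median.

* **M-ratio.**  ``M = k / (r + 1)`` with ``r`` the allele-size range in
  repeat units; bottlenecks depress M because rare alleles vanish faster
  than the range contracts.  A critical value ``M_c`` is the lower empirical
  quantile of mean M over equilibrium datasets simulated at the
  pre-bottleneck ``theta = 4 * N_e * mu``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coalescent import Genealogy, MutationModel, scaled_coalescent_tree
from .genotype_io import GenotypeTable

__all__ = [
    "TPMConfig",
    "MRatioConfig",
    "EquilibriumHet",
    "HetExcessResult",
    "MRatioResult",
    "MCritical",
    "equilibrium_het_given_k",
    "equilibrium_dataset",
    "het_excess_test",
    "m_ratio",
    "m_critical",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TPMConfig:
    """Two-phase mutation model settings for the equilibrium simulations."""

    p_single: float = 0.78
    multi_step_mean: float = 3.1
    n_iter: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_single <= 1.0):
            raise ValueError("p_single must lie in [0, 1]")
        if self.n_iter < 1000:
            raise ValueError("n_iter must be >= 1000 for a stable equilibrium estimate")

    def as_model(self) -> MutationModel:
        return MutationModel(
            p_single=self.p_single,
            multi_step_mean=self.multi_step_mean,
            state_bounds=None,
        )


@dataclass(frozen=True)
class MRatioConfig:
    """Configuration of the simulated M-ratio critical value."""

    theta_range: tuple[float, float] = (0.1, 0.2)
    mu: float = 5e-4
    tpm: TPMConfig = field(default_factory=TPMConfig)
    quantile: float = 0.05

    def __post_init__(self) -> None:
        lo, hi = self.theta_range
        if lo <= 0 or hi < lo:
            raise ValueError("theta_range must be positive with lo <= hi")
        if not (0.0 < self.quantile < 0.5):
            raise ValueError("quantile must lie in (0, 0.5)")


# ---------------------------------------------------------------------------
# Equilibrium heterozygosity given k
# ---------------------------------------------------------------------------

@dataclass
class EquilibriumHet:
    k: int
    n: int
    mean: float
    sd: float
    n_iter: int
    uninformative: bool = False


def _condition_tree_on_k(
    tree: Genealogy,
    k: int,
    model: MutationModel,
    rng: np.random.Generator,
    max_mutations: int,
) -> np.ndarray | None:
    """Place mutations one at a time until exactly k distinct leaf states.

    Returns leaf states, or None if k was never hit within ``max_mutations``
    (homoplasy can make the distinct count skip over k; the caller then
    resamples a genealogy).
    """
    bl = tree.branch_lengths
    cum = np.cumsum(bl)
    total = cum[-1]
    desc = tree.descendant_leaves()
    states = np.zeros(tree.n_leaves, dtype=np.int64)
    distinct = 1
    for _ in range(max_mutations):
        if distinct == k:
            return states
        b = int(np.searchsorted(cum, rng.random() * total))
        step = int(model.draw_steps(1, rng)[0])
        states[desc[b]] += step
        distinct = len(np.unique(states))
    return states if distinct == k else None


def _simulate_locus(
    n: int, theta: float, model: MutationModel, rng: np.random.Generator
) -> tuple[int, float]:
    """(allele count, gene diversity) of one equilibrium locus at ``theta``."""
    tree = scaled_coalescent_tree(n, rng)
    bl = tree.branch_lengths
    cum = np.cumsum(bl)
    n_mut = rng.poisson(0.5 * theta * cum[-1])
    states = np.zeros(n, dtype=np.int64)
    if n_mut:
        desc = tree.descendant_leaves()
        steps = model.draw_steps(n_mut, rng)
        for m in range(n_mut):
            b = int(np.searchsorted(cum, rng.random() * cum[-1]))
            states[desc[b]] += int(steps[m])
    _, counts = np.unique(states, return_counts=True)
    p = counts / n
    return len(counts), 1.0 - float(np.sum(p**2))


_EK_CURVES: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _expected_k_curve(n: int, tpm: TPMConfig) -> tuple[np.ndarray, np.ndarray]:
    """Simulated E[K | theta] on a log-spaced theta grid (cached per n, model)."""
    key = (n, tpm.p_single, tpm.multi_step_mean)
    if key not in _EK_CURVES:
        model = tpm.as_model()
        rng = np.random.default_rng([12345, n])
        grid = np.geomspace(0.02, 500.0, 24)
        ek = np.array(
            [np.mean([_simulate_locus(n, th, model, rng)[0] for _ in range(400)])
             for th in grid]
        )
        ek = np.maximum.accumulate(ek)  # enforce monotonicity against MC noise
        _EK_CURVES[key] = (np.log(grid), ek)
    return _EK_CURVES[key]


def theta_matching_k(k: float, n: int, tpm: TPMConfig = TPMConfig()) -> float:
    """Theta at which the equilibrium expected allele count equals ``k``.

    ``k`` may be fractional (e.g. a mean allele count across loci, giving a
    multilocus theta estimate).
    """
    log_grid, ek = _expected_k_curve(n, tpm)
    return float(np.exp(np.interp(k, ek, log_grid)))


def _quantize_theta(theta: float, step: float = 0.25) -> float:
    """Round theta on a log grid so conditional simulations cache well.

    The conditional distribution of H given k varies slowly with theta
    (dH/dln(theta) is a few hundredths), so a quarter-log-unit grid costs
    well under 0.01 in H while letting many datasets share one pool.
    """
    return float(np.exp(np.round(np.log(theta) / step) * step))


# pooled equilibrium simulations per (n, theta): one pool serves every k
_POOL_CACHE: dict[tuple, dict[int, tuple[float, float, int]]] = {}


def _pooled_conditional(
    n: int, theta: float, tpm: TPMConfig, seed: int
) -> dict[int, tuple[float, float, int]]:
    """Bin a pool of equilibrium loci at fixed theta by allele count.

    Returns ``{k: (mean H, sd H, count)}`` from ``30 * n_iter`` simulated
    loci; cached, so all loci (and datasets) sharing (n, theta) reuse it.
    """
    key = (n, theta, tpm.p_single, tpm.multi_step_mean, tpm.n_iter, seed)
    if key not in _POOL_CACHE:
        model = tpm.as_model()
        rng = np.random.default_rng([seed, n, int(1e6 * theta)])
        m = 30 * tpm.n_iter
        ks = np.empty(m, dtype=np.int64)
        hs = np.empty(m)
        for i in range(m):
            ks[i], hs[i] = _simulate_locus(n, theta, model, rng)
        bins: dict[int, tuple[float, float, int]] = {}
        for k in np.unique(ks):
            sel = hs[ks == k]
            bins[int(k)] = (
                float(sel.mean()),
                float(sel.std(ddof=1)) if sel.size > 1 else 0.0,
                int(sel.size),
            )
        _POOL_CACHE[key] = bins
    return _POOL_CACHE[key]


def equilibrium_het_given_k(
    k: int,
    n: int,
    tpm: TPMConfig = TPMConfig(),
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
    method: str = "theta-matched",
    theta: float | None = None,
) -> EquilibriumHet:
    """Mean and SD of equilibrium gene diversity given ``k`` alleles in ``n`` copies.

    ``method='theta-matched'`` (default) conditions on exactly ``k`` allelic
    states by rejection at a fixed theta: either the supplied ``theta``
    (e.g. a multilocus estimate — loci of one population share theta) or,
    if omitted, the theta at which the equilibrium expected allele count
    equals ``k``.  Under the stepwise models the conditional distribution of
    H given k depends on theta, so this plug-in keeps the test calibrated.
    ``method='sequential'`` instead drops mutations one at a time at uniform
    points on the genealogy until exactly ``k`` states exist (the
    constructive, theta-free variant; slightly biased under homoplasy).

    ``k == n`` is deterministic (every copy distinct, ``H = 1 - 1/n``);
    ``k == 1`` is degenerate at 0 and flagged uninformative.
    """
    if k > n:
        raise ValueError(f"cannot have k={k} alleles among n={n} gene copies")
    if k < 1 or n < 2:
        raise ValueError("need k >= 1 and n >= 2")
    if k == 1:
        return EquilibriumHet(k, n, 0.0, 0.0, tpm.n_iter, uninformative=True)
    if k == n:
        return EquilibriumHet(k, n, 1.0 - 1.0 / n, 0.0, tpm.n_iter)
    if rng is None:
        rng = np.random.default_rng(seed)
    model = tpm.as_model()
    hets = np.empty(tpm.n_iter)
    if method == "sequential":
        max_mut = 200 + 60 * k
        for it in range(tpm.n_iter):
            while True:
                tree = scaled_coalescent_tree(n, rng)
                states = _condition_tree_on_k(tree, k, model, rng, max_mut)
                if states is not None:
                    break
            _, counts = np.unique(states, return_counts=True)
            p = counts / n
            hets[it] = 1.0 - float(np.sum(p**2))
    elif method == "theta-matched":
        th = theta_matching_k(k, n, tpm) if theta is None else theta
        max_attempts = 150 * tpm.n_iter
        got = 0
        for _ in range(max_attempts):
            kk, h = _simulate_locus(n, th, model, rng)
            if kk == k:
                hets[got] = h
                got += 1
                if got == tpm.n_iter:
                    break
        if got < tpm.n_iter:
            if got < 50 and theta is not None:
                # k is far in the tail for the multilocus theta; fall back to
                # the single-locus plug-in where acceptance is high
                return equilibrium_het_given_k(
                    k, n, tpm, rng=rng, method="theta-matched", theta=None
                )
            log.warning(
                "equilibrium_het_given_k(k=%d, n=%d): only %d accepted replicates",
                k, n, got,
            )
            hets = hets[:max(got, 2)]
    else:
        raise ValueError(f"unknown method {method!r}")
    return EquilibriumHet(k, n, float(hets.mean()), float(hets.std(ddof=1)), tpm.n_iter)


# memoized across loci/populations/datasets: the conditional distribution
# depends only on (k, n, theta, mutation model, iteration count, seed)
_EQ_CACHE: dict[tuple, EquilibriumHet] = {}


def _equilibrium_cached(
    k: int, n: int, theta: float | None, tpm: TPMConfig, seed: int
) -> EquilibriumHet:
    key = (k, n, theta, tpm.p_single, tpm.multi_step_mean, tpm.n_iter, seed)
    if key not in _EQ_CACHE:
        # decorrelate streams across (k, n) while staying reproducible
        sub = np.random.default_rng([seed, k, n])
        _EQ_CACHE[key] = equilibrium_het_given_k(k, n, tpm, rng=sub, theta=theta)
    return _EQ_CACHE[key]


# ---------------------------------------------------------------------------
# Heterozygosity-excess test
# ---------------------------------------------------------------------------

@dataclass
class HetExcessResult:
    population: str
    p_value: float
    d_values: pd.Series           # standardized (H_obs - mean H_eq)/SD per locus
    n_loci_used: int
    skipped_loci: list[str]
    exact: bool
    seed: int
    n_iter: int


def het_excess_test(
    table: GenotypeTable,
    population: str,
    tpm: TPMConfig = TPMConfig(),
    seed: int = 0,
) -> HetExcessResult:
    """One-tailed Wilcoxon signed-rank test for heterozygosity excess.

    Monomorphic loci are skipped (logged).  Loci of one population share a
    single theta, so the equilibrium expectation per locus is conditioned at
    a multilocus theta matched to the mean allele count across all loci.
    The exact Wilcoxon null is used for up to 25 informative loci, the
    normal approximation beyond.
    """
    per_locus: list[tuple[str, int, int, float]] = []
    all_k: list[int] = []
    for j, locus in enumerate(table.loci):
        states, counts = table.allele_counts(population, j)
        n = int(counts.sum())
        k = len(states)
        all_k.append(k)
        if k < 2:
            continue
        p = counts / n
        h_obs = 1.0 - float(np.sum(p**2))
        per_locus.append((locus, k, n, h_obs))
    skipped = [l for l, kk in zip(table.loci, all_k) if kk < 2]
    for locus in skipped:
        log.info("het_excess_test: skipping monomorphic locus %s in %s", locus, population)
    n_modal = int(np.median([n for _, _, n, _ in per_locus])) if per_locus else 0
    theta_hat = (
        _quantize_theta(theta_matching_k(float(np.mean(all_k)), n_modal, tpm))
        if per_locus
        else None
    )
    d_vals: dict[str, float] = {}
    for locus, k, n, h_obs in per_locus:
        pool = _pooled_conditional(n, theta_hat, tpm, seed)
        entry = pool.get(k)
        if entry is not None and entry[2] >= 200:
            mean, sd, _ = entry
        else:
            # k in the tail for the multilocus theta: condition at the
            # single-locus plug-in theta instead, where acceptance is high
            eq = _equilibrium_cached(k, n, None, tpm, seed)
            mean, sd = eq.mean, eq.sd
        sd = sd if sd > 0 else 1e-12
        d_vals[locus] = (h_obs - mean) / sd
    if len(d_vals) < 4:
        raise ValueError(
            f"population {population!r} has only {len(d_vals)} polymorphic loci; "
            "the Wilcoxon test needs at least 4"
        )
    d = np.array(list(d_vals.values()))
    exact = len(d) <= 25
    res = stats.wilcoxon(
        d, alternative="greater", method="exact" if exact else "approx"
    )
    return HetExcessResult(
        population=population,
        p_value=float(res.pvalue),
        d_values=pd.Series(d_vals),
        n_loci_used=len(d_vals),
        skipped_loci=skipped,
        exact=exact,
        seed=seed,
        n_iter=tpm.n_iter,
    )


# ---------------------------------------------------------------------------
# M-ratio
# ---------------------------------------------------------------------------

@dataclass
class MRatioResult:
    population: str
    per_locus: pd.Series
    mean: float


def m_ratio(table: GenotypeTable, population: str) -> MRatioResult:
    """Per-locus and mean ``M = k / (range + 1)`` for one population.

    Allele states must be in repeat units.  A monomorphic locus has M = 1 by
    convention (logged).
    """
    vals: dict[str, float] = {}
    for j, locus in enumerate(table.loci):
        states, _ = table.allele_counts(population, j)
        if len(states) == 0:
            raise ValueError(f"locus {locus!r} untyped in population {population!r}")
        if len(states) == 1:
            log.info("m_ratio: monomorphic locus %s in %s counted as M = 1", locus, population)
            vals[locus] = 1.0
            continue
        r = int(states.max() - states.min())
        vals[locus] = len(states) / (r + 1)
    s = pd.Series(vals)
    return MRatioResult(population=population, per_locus=s, mean=float(s.mean()))


def equilibrium_dataset(
    n_diploids: int,
    n_loci: int,
    theta: float,
    tpm: TPMConfig = TPMConfig(),
    seed: int = 0,
) -> GenotypeTable:
    """One single-population dataset at mutation-drift equilibrium.

    Simulates ``n_loci`` independent loci for ``2 * n_diploids`` gene copies
    at the given ``theta = 4 * N_e * mu`` under the TPM on an unbounded
    lattice (states are offset to stay positive).  Used for calibration of
    the heterozygosity-excess test and anywhere an equilibrium null is
    needed.
    """
    rng = np.random.default_rng(seed)
    model = tpm.as_model()
    n_copies = 2 * n_diploids
    alleles = np.empty((n_diploids, n_loci, 2), dtype=np.int64)
    offset = 1000  # keep states positive on the unbounded lattice
    for j in range(n_loci):
        tree = scaled_coalescent_tree(n_copies, rng)
        bl = tree.branch_lengths
        cum = np.cumsum(bl)
        n_mut = rng.poisson(0.5 * theta * cum[-1])
        states = np.zeros(n_copies, dtype=np.int64)
        if n_mut:
            desc = tree.descendant_leaves()
            steps = model.draw_steps(n_mut, rng)
            for m in range(n_mut):
                b = int(np.searchsorted(cum, rng.random() * cum[-1]))
                states[desc[b]] += int(steps[m])
        alleles[:, j, :] = (states + offset).reshape(n_diploids, 2)
    return GenotypeTable(
        individuals=[f"eq_{i + 1:03d}" for i in range(n_diploids)],
        loci=[f"L{j + 1:02d}" for j in range(n_loci)],
        alleles=alleles,
        populations=["eq"] * n_diploids,
    )


@dataclass
class MCritical:
    value: float
    quantile: float
    samples: np.ndarray  # simulated mean M per equilibrium dataset

    @property
    def median(self) -> float:
        return float(np.median(self.samples))


def _equilibrium_locus_m(
    n_copies: int, theta: float, model: MutationModel, rng: np.random.Generator
) -> float:
    """Mean-M building block: one equilibrium locus, M = k/(r+1)."""
    # Branch lengths in units of 2N generations; mutations at theta/2 per
    # lineage per unit time.  Descendant sets are only needed when mutations land.
    tree = scaled_coalescent_tree(n_copies, rng)
    bl = tree.branch_lengths
    cum = np.cumsum(bl)
    n_mut = rng.poisson(0.5 * theta * cum[-1])
    if n_mut == 0:
        return 1.0  # monomorphic by convention
    desc = tree.descendant_leaves()
    states = np.zeros(n_copies, dtype=np.int64)
    steps = model.draw_steps(n_mut, rng)
    for m in range(n_mut):
        b = int(np.searchsorted(cum, rng.random() * cum[-1]))
        states[desc[b]] += int(steps[m])
    uniq = np.unique(states)
    if len(uniq) == 1:
        return 1.0
    return len(uniq) / (int(uniq.max() - uniq.min()) + 1)


def m_critical(
    config: MRatioConfig,
    n_loci: int,
    n_diploids: int,
    n_sims: int = 10000,
    seed: int = 0,
) -> MCritical:
    """Simulated critical value of mean M under mutation-drift equilibrium.

    For each simulated dataset theta is drawn uniformly on
    ``config.theta_range``; ``n_loci`` independent equilibrium loci are
    simulated under the TPM for a sample of ``n_diploids`` individuals, and
    mean M recorded.  ``M_c`` is the ``config.quantile`` empirical quantile.
    """
    if n_sims < 1000:
        raise ValueError("n_sims must be >= 1000")
    rng = np.random.default_rng(seed)
    model = config.tpm.as_model()
    n_copies = 2 * n_diploids
    lo, hi = config.theta_range
    means = np.empty(n_sims)
    for s in range(n_sims):
        theta = rng.uniform(lo, hi)
        acc = 0.0
        for _ in range(n_loci):
            acc += _equilibrium_locus_m(n_copies, theta, model, rng)
        means[s] = acc / n_loci
    return MCritical(
        value=float(np.quantile(means, config.quantile)),
        quantile=config.quantile,
        samples=means,
    )
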
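"""Structured-coalescent simulation of diploid microsatellite data.

The simulator runs the coalescent backwards in time over named demes with
piecewise-constant effective sizes.  Lineages within a deme of size ``N``
coalesce pairwise at rate ``k(k-1)/2 / (2N)`` per generation (continuous-time
approximation of the Wright-Fisher model); at a merge event all lineages of
the daughter demes relocate to the ancestral deme.  Mutations are dropped on
the resulting genealogy as a Poisson process and shift the allele state on a
repeat-unit lattice under a generalized stepwise model: single steps with
probability ``p_single``, otherwise geometric-tailed multi-step jumps, with
reflecting state bounds.

A scaled single-population coalescent (time in units of 2N generations,
mutation rate theta/2 per lineage per unit time) is also provided; it is the
workhorse for the mutation-drift-equilibrium machinery of the bottleneck
tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genotype_io import GenotypeTable

__all__ = [
    "Deme",
    "MergeEvent",
    "Scenario",
    "MutationModel",
    "Genealogy",
    "simulate_genealogy",
    "scaled_coalescent_tree",
    "mutate",
    "simulate_dataset",
]


# ---------------------------------------------------------------------------
# Demography
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Deme:
    """A deme with a piecewise-constant size history.

    ``sizes`` is a tuple of ``(start_time, size)`` pairs in generations before
    present, ascending, first start at 0; each size applies from its start
    time backwards until the next entry (the last extends to infinity).
    """

    name: str
    sizes: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.sizes or self.sizes[0][0] != 0:
            raise ValueError(f"deme {self.name!r}: first epoch must start at time 0")
        times = [t for t, _ in self.sizes]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"deme {self.name!r}: epoch times must be strictly increasing")
        if any(s <= 0 for _, s in self.sizes):
            raise ValueError(f"deme {self.name!r}: every epoch needs a positive size")

    def size_at(self, t: float) -> float:
        size = self.sizes[0][1]
        for start, s in self.sizes:
            if start <= t:
                size = s
            else:
                break
        return size

    def next_change_after(self, t: float) -> float:
        for start, _ in self.sizes:
            if start > t:
                return start
        return np.inf


@dataclass(frozen=True)
class MergeEvent:
    """At ``time`` (generations BP) all lineages of ``daughters`` move to ``ancestor``."""

    time: float
    daughters: tuple[str, ...]
    ancestor: str

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("merge event times must be strictly positive")


@dataclass(frozen=True)
class Scenario:
    """A demographic model: demes, merge events and diploid sample sizes."""

    demes: tuple[Deme, ...]
    events: tuple[MergeEvent, ...]
    sample_sizes: tuple[tuple[str, int], ...]  # (deme, diploids), ordered

    def __post_init__(self) -> None:
        names = {d.name for d in self.demes}
        if len(names) != len(self.demes):
            raise ValueError("duplicate deme names")
        for ev in self.events:
            for d in ev.daughters + (ev.ancestor,):
                if d not in names:
                    raise ValueError(f"merge event references unknown deme {d!r}")
        for deme, n in self.sample_sizes:
            if deme not in names:
                raise ValueError(f"sample from unknown deme {deme!r}")
            if n < 1:
                raise ValueError("sample sizes must be >= 1")
        times = [ev.time for ev in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("merge events must be sorted by time")
        # after all merges a single lineage-bearing deme must remain
        alive = {d for d, _ in self.sample_sizes}
        for ev in self.events:
            if alive & set(ev.daughters):
                alive -= set(ev.daughters)
                alive.add(ev.ancestor)
        if len(alive) != 1:
            raise ValueError(
                f"scenario does not coalesce to a single root deme (left: {sorted(alive)})"
            )

    def deme(self, name: str) -> Deme:
        for d in self.demes:
            if d.name == name:
                return d
        raise KeyError(name)

    @property
    def n_copies(self) -> int:
        return 2 * sum(n for _, n in self.sample_sizes)


@dataclass(frozen=True)
class MutationModel:
    """Generalized stepwise mutation on a bounded repeat-unit lattice.

    Parameters
    ----------
    mean_rate
        Mean per-locus per-generation mutation rate (mu-bar).
    rate_shape
        Shape of the Gamma distribution of per-locus rates around the mean.
    p_single
        Probability a mutation is a single repeat step; otherwise the jump is
        ``1 + Geometric`` (support >= 2) with mean ``multi_step_mean``.
    multi_step_mean
        Mean magnitude of multi-step jumps (> 2).
    state_bounds
        ``(lo, hi)`` inclusive contiguous allele-state range with reflecting
        boundaries, or ``None`` for an unbounded lattice.
    """

    mean_rate: float = 5e-4
    rate_shape: float = 2.0
    p_single: float = 0.78
    multi_step_mean: float = 3.1
    state_bounds: tuple[int, int] | None = (10, 49)

    def __post_init__(self) -> None:
        if not (0.0 < self.p_single <= 1.0):
            raise ValueError("p_single must be in (0, 1]")
        if self.p_single < 1.0 and self.multi_step_mean <= 2.0:
            raise ValueError("multi_step_mean must exceed 2 for a geometric tail")
        if self.state_bounds is not None:
            lo, hi = self.state_bounds
            if hi - lo + 1 < 2:
                raise ValueError("state bounds must span at least 2 states")

    @property
    def root_state(self) -> int:
        if self.state_bounds is None:
            return 0
        lo, hi = self.state_bounds
        return (lo + hi) // 2

    def draw_locus_rate(self, rng: np.random.Generator) -> float:
        if self.rate_shape is None or self.rate_shape <= 0:
            return self.mean_rate
        return float(rng.gamma(self.rate_shape, self.mean_rate / self.rate_shape))

    def draw_steps(self, m: int, rng: np.random.Generator) -> np.ndarray:
        """Signed step sizes for ``m`` mutations."""
        mag = np.ones(m, dtype=np.int64)
        multi = rng.random(m) >= self.p_single
        k = int(multi.sum())
        if k:
            # jump = 1 + Geometric(p) with mean multi_step_mean  =>  p = 1/(mean-1)
            p = 1.0 / (self.multi_step_mean - 1.0)
            mag[multi] = 1 + rng.geometric(p, size=k)
        sign = rng.integers(0, 2, size=m) * 2 - 1
        return mag * sign


def reflect_state(x: int, lo: int, hi: int) -> int:
    """Fold an integer onto [lo, hi] by reflection (triangle wave)."""
    width = hi - lo
    if width == 0:
        return lo
    period = 2 * width
    y = (x - lo) % period
    if y > width:
        y = period - y
    return lo + y


# ---------------------------------------------------------------------------
# Genealogies
# ---------------------------------------------------------------------------

@dataclass
class Genealogy:
    """A coalescent tree over sampled gene copies.

    Nodes ``0..n_leaves-1`` are leaves; internal nodes are appended in
    coalescence order; the root is the last node.  ``parent[root] == -1``.
    ``time`` is in the simulation's time unit (generations for structured
    scenarios, units of 2N for the scaled single-deme tree).
    """

    n_leaves: int
    parent: np.ndarray
    time: np.ndarray
    leaf_demes: list[str] | None = None

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    @property
    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node (root entry 0)."""
        bl = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        bl[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return bl

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths.sum())

    @property
    def tmrca(self) -> float:
        return float(self.time[-1])

    def descendant_leaves(self) -> list[np.ndarray]:
        """Leaf index array subtended by each node."""
        desc: list[list[int] | None] = [None] * self.n_nodes
        for i in range(self.n_leaves):
            desc[i] = [i]
        for i in range(self.n_leaves, self.n_nodes):
            desc[i] = []
        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes - 1):
            children[self.parent[v]].append(v)
        # nodes are in coalescence order, so children always precede parents
        for v in range(self.n_leaves, self.n_nodes):
            acc: list[int] = []
            for c in children[v]:
                acc.extend(desc[c])  # type: ignore[arg-type]
            desc[v] = acc
        return [np.asarray(d, dtype=np.intp) for d in desc]  # type: ignore[arg-type]


def scaled_coalescent_tree(n: int, rng: np.random.Generator) -> Genealogy:
    """Single-deme Kingman coalescent with time in units of 2N generations."""
    if n < 2:
        raise ValueError("need at least 2 gene copies")
    parent = np.full(2 * n - 1, -1, dtype=np.intp)
    time = np.zeros(2 * n - 1)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i = rng.integers(k)
        j = rng.integers(k - 1)
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        for idx in sorted((i, j), reverse=True):
            active.pop(idx)
        active.append(nxt)
        nxt += 1
    return Genealogy(n_leaves=n, parent=parent, time=time)


def simulate_genealogy(scenario: Scenario, seed_or_rng) -> Genealogy:
    """Simulate one genealogy (times in generations) under a structured scenario."""
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator
    ) else seed_or_rng

    n = scenario.n_copies
    parent = np.full(2 * n - 1, -1, dtype=np.intp)
    time = np.zeros(2 * n - 1)
    leaf_demes: list[str] = []
    pools: dict[str, list[int]] = {d.name: [] for d in scenario.demes}
    node = 0
    for deme, diploids in scenario.sample_sizes:
        for _ in range(2 * diploids):
            pools[deme].append(node)
            leaf_demes.append(deme)
            node += 1
    nxt = n
    t = 0.0
    pending = list(scenario.events)

    def total_active() -> int:
        return sum(len(v) for v in pools.values())

    while total_active() > 1:
        rates: dict[str, float] = {}
        boundary = pending[0].time if pending else np.inf
        for name, lin in pools.items():
            k = len(lin)
            if k >= 2:
                deme = scenario.deme(name)
                rates[name] = k * (k - 1) / 2.0 / (2.0 * deme.size_at(t))
                boundary = min(boundary, deme.next_change_after(t))
        R = sum(rates.values())
        if R > 0:
            dt = rng.exponential(1.0 / R)
        else:
            dt = np.inf
        if t + dt >= boundary:
            if not np.isfinite(boundary):
                raise RuntimeError(
                    "lineages cannot coalesce: remaining lineages are isolated in "
                    "separate demes with no further merge events"
                )
            t = boundary
            while pending and pending[0].time <= t:
                ev = pending.pop(0)
                for d in ev.daughters:
                    pools[ev.ancestor].extend(pools[d])
                    pools[d] = []
            continue
        t += dt
        # choose deme proportional to rate, then a uniform pair within it
        u = rng.random() * R
        acc = 0.0
        chosen = next(iter(rates))
        for name, r in rates.items():
            acc += r
            if u <= acc:
                chosen = name
                break
        lin = pools[chosen]
        i = rng.integers(len(lin))
        j = rng.integers(len(lin) - 1)
        if j >= i:
            j += 1
        a, b = lin[i], lin[j]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        for idx in sorted((i, j), reverse=True):
            lin.pop(idx)
        lin.append(nxt)
        nxt += 1
    return Genealogy(n_leaves=n, parent=parent, time=time, leaf_demes=leaf_demes)


# ---------------------------------------------------------------------------
# Mutation
# ---------------------------------------------------------------------------

def mutate(
    genealogy: Genealogy,
    model: MutationModel,
    rng: np.random.Generator,
    rate: float | None = None,
) -> np.ndarray:
    """Drop Poisson mutations on the genealogy; return leaf allele states.

    ``rate`` is the per-generation locus rate (defaults to the model mean);
    branch lengths must be in the same time unit as the rate.  The root state
    is the midpoint of the state bounds (0 if unbounded); each mutation shifts
    the state by a signed stepwise jump with reflection at the bounds.
    """
    mu = model.mean_rate if rate is None else rate
    bl = genealogy.branch_lengths
    total = bl.sum()
    n_mut = rng.poisson(mu * total) if total > 0 else 0
    root = model.root_state
    n_nodes = genealogy.n_nodes
    states = np.full(n_nodes, root, dtype=np.int64)
    if n_mut == 0:
        return states[: genealogy.n_leaves].copy()

    cum = np.cumsum(bl)
    branch_of = np.searchsorted(cum, rng.random(n_mut) * total)
    steps = model.draw_steps(n_mut, rng)
    per_branch: dict[int, list[int]] = {}
    for b, s in zip(branch_of, steps):
        per_branch.setdefault(int(b), []).append(int(s))

    # top-down: parents are created after children, so iterate high -> low
    bounds = model.state_bounds
    for v in range(n_nodes - 2, -1, -1):
        p = genealogy.parent[v]
        s = states[p]
        muts = per_branch.get(v)
        if muts:
            if bounds is None:
                s += sum(muts)
            else:
                lo, hi = bounds
                for d in muts:
                    s = reflect_state(s + d, lo, hi)
        states[v] = s
    return states[: genealogy.n_leaves].copy()


def simulate_dataset(
    scenario: Scenario,
    model: MutationModel,
    n_loci: int,
    master_seed,
    locus_names: Sequence[str] | None = None,
) -> GenotypeTable:
    """Simulate a diploid multi-locus dataset; deterministic given ``master_seed``.

    Per locus the rate is drawn from the across-locus Gamma distribution, a
    genealogy is simulated, mutations are dropped, and consecutive gene copies
    within each deme are paired into diploids.  Deme names become population
    labels.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1 (the GENEPOP writer rejects empty-locus tables)")
    rng = np.random.default_rng(master_seed)
    n_ind = sum(n for _, n in scenario.sample_sizes)
    alleles = np.empty((n_ind, n_loci, 2), dtype=np.int64)
    for j in range(n_loci):
        locus_rate = model.draw_locus_rate(rng)
        gen = simulate_genealogy(scenario, rng)
        states = mutate(gen, model, rng, rate=locus_rate)
        alleles[:, j, :] = states.reshape(n_ind, 2)
    individuals, populations = [], []
    for deme, n in scenario.sample_sizes:
        for i in range(n):
            individuals.append(f"{deme}_{i + 1:03d}")
            populations.append(deme)
    loci = (
        list(locus_names)
        if locus_names is not None
        else [f"L{j + 1:02d}" for j in range(n_loci)]
    )
    return GenotypeTable(individuals, loci, alleles, populations)
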
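"""Genetic differentiation: Weir-Cockerham F_ST, chord distances, NJ trees.

F_ST is the Weir & Cockerham (1984) theta estimator, accumulated over
alleles and loci as ratios of summed variance components.  Distances use
the Cavalli-Sforza & Edwards chord distance

    d_locus = (2/pi) * sqrt(2 * (1 - sum_a sqrt(x_a * y_a)))

averaged over loci.  Neighbor-joining is implemented with deterministic
tie-breaking (smallest Q, then lexicographic label order); bootstrap
supports are obtained by resampling loci with replacement and mapping
bipartition frequencies onto the full-data topology.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import GenotypeTable

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "TreeWithSupport",
    "fst",
    "FstResult",
    "fst_permutation_p",
    "dce_distance",
    "nj_tree",
    "bootstrap_tree",
]

log = logging.getLogger(__name__)

DCE_LOCUS_MAX = (2.0 / np.pi) * np.sqrt(2.0)  # per-locus chord distance bound


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if not np.all(np.isfinite(v)):
            raise ValueError("distance matrix entries must be finite")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_phylip(self) -> str:
        lines = [f"{len(self.labels)}"]
        for i, lab in enumerate(self.labels):
            lines.append(
                f"{lab:<12s}" + " ".join(f"{x:.6f}" for x in self.values[i])
            )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def _locus_components(
    freqs: list[dict[int, float]],
    het: list[dict[int, float]],
    sizes: list[int],
) -> tuple[float, float]:
    """Summed (a, a+b+c) variance components over alleles at one locus.

    ``freqs[i]`` maps allele -> frequency in population i, ``het[i]`` maps
    allele -> proportion of individuals heterozygous for that allele,
    ``sizes[i]`` is the number of genotyped individuals.
    """
    r = len(sizes)
    n = np.asarray(sizes, dtype=float)
    nbar = n.mean()
    if nbar <= 1 or r < 2:
        return 0.0, 0.0
    nc = (r * nbar - np.sum(n**2) / (r * nbar)) / (r - 1)
    alleles = sorted(set().union(*[f.keys() for f in freqs]))
    a_sum = 0.0
    abc_sum = 0.0
    for al in alleles:
        p = np.array([f.get(al, 0.0) for f in freqs])
        h = np.array([hh.get(al, 0.0) for hh in het])
        pbar = float(np.sum(n * p) / (r * nbar))
        s2 = float(np.sum(n * (p - pbar) ** 2) / ((r - 1) * nbar))
        hbar = float(np.sum(n * h) / (r * nbar))
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1))
            * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - ((r - 1) / r) * s2
            - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
        a_sum += a
        abc_sum += a + b + c
    return a_sum, abc_sum


def _pop_locus_summary(table: GenotypeTable, pop: str, j: int):
    geno = table.genotypes(pop, j)
    n = geno.shape[0]
    if n == 0:
        return None
    copies = geno.ravel()
    states, counts = np.unique(copies, return_counts=True)
    freqs = {int(s): c / copies.size for s, c in zip(states, counts)}
    het: dict[int, float] = {}
    is_het = geno[:, 0] != geno[:, 1]
    for s in states:
        carries = is_het & ((geno[:, 0] == s) | (geno[:, 1] == s))
        het[int(s)] = float(np.sum(carries)) / n
    return freqs, het, n


@dataclass
class FstResult:
    global_theta: float
    pairwise: DistanceMatrix | None
    per_locus: dict[str, float]
    low_information: list[tuple[str, str]] = field(default_factory=list)


def _multilocus_theta(table: GenotypeTable, pops: list[str]) -> tuple[float, dict[str, float]]:
    num = 0.0
    den = 0.0
    per_locus: dict[str, float] = {}
    for j, locus in enumerate(table.loci):
        summaries = []
        for pop in pops:
            s = _pop_locus_summary(table, pop, j)
            if s is not None:
                summaries.append(s)
        if len(summaries) < 2:
            continue
        freqs = [s[0] for s in summaries]
        het = [s[1] for s in summaries]
        sizes = [s[2] for s in summaries]
        a, abc = _locus_components(freqs, het, sizes)
        if abc != 0.0:
            per_locus[locus] = a / abc
        num += a
        den += abc
    theta = num / den if den != 0.0 else 0.0
    return float(theta), per_locus


def fst(table: GenotypeTable, pops: list[str] | None = None, pairwise: bool = True) -> FstResult:
    """Global and pairwise Weir-Cockerham theta (multilocus ratio of sums)."""
    pops = list(pops) if pops is not None else table.population_labels
    if len(pops) < 2:
        raise ValueError("F_ST needs at least 2 populations")
    global_theta, per_locus = _multilocus_theta(table, pops)
    pw = None
    low_info: list[tuple[str, str]] = []
    if pairwise:
        m = np.zeros((len(pops), len(pops)))
        for i in range(len(pops)):
            for k in range(i + 1, len(pops)):
                th, pl = _multilocus_theta(table, [pops[i], pops[k]])
                if not pl:
                    low_info.append((pops[i], pops[k]))
                    log.warning("pair (%s, %s) monomorphic at all shared loci", pops[i], pops[k])
                m[i, k] = m[k, i] = th
        # pairwise theta can be slightly negative; DistanceMatrix only asserts
        # symmetry, zero diagonal and finiteness
        pw = DistanceMatrix(labels=pops, values=m)
    return FstResult(global_theta=global_theta, pairwise=pw, per_locus=per_locus,
                     low_information=low_info)


def fst_permutation_p(
    table: GenotypeTable,
    pair: tuple[str, str],
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p-value for pairwise theta: individuals shuffled between the pair."""
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    a, b = pair
    theta_obs, per_locus = _multilocus_theta(table, [a, b])
    if not per_locus:
        warnings.warn(f"pair ({a}, {b}) is monomorphic; p-value is 1", stacklevel=2)
        return 1.0
    idx = np.concatenate([table.pop_indices(a), table.pop_indices(b)])
    n_a = table.pop_indices(a).size
    sub_alleles = table.alleles[idx]
    loci = table.loci
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(idx.size)
        populations = ["A"] * n_a + ["B"] * (idx.size - n_a)
        shuffled = GenotypeTable(
            individuals=[f"i{t}" for t in range(idx.size)],
            loci=list(loci),
            alleles=sub_alleles[perm],
            populations=populations,
        )
        theta_p, _ = _multilocus_theta(shuffled, ["A", "B"])
        if theta_p >= theta_obs:
            count += 1
    return float((1 + count) / (1 + n_perm))


# ---------------------------------------------------------------------------
# Cavalli-Sforza & Edwards chord distance
# ---------------------------------------------------------------------------

def _freq_table(table: GenotypeTable) -> list[list[dict[int, float] | None]]:
    """Per population (in label order) per locus: allele frequency dict or None."""
    out = []
    for pop in table.population_labels:
        row = []
        for j in range(table.n_loci):
            states, counts = table.allele_counts(pop, j)
            if counts.size == 0:
                row.append(None)
            else:
                tot = counts.sum()
                row.append({int(s): c / tot for s, c in zip(states, counts)})
        out.append(row)
    return out


def _dce_locus(x: dict[int, float], y: dict[int, float]) -> float:
    s = 0.0
    for al, xa in x.items():
        ya = y.get(al)
        if ya:
            s += np.sqrt(xa * ya)
    inner = max(0.0, 1.0 - s)
    return (2.0 / np.pi) * np.sqrt(2.0 * inner)


def dce_per_locus(table: GenotypeTable) -> np.ndarray:
    """(n_pairs, n_loci) per-locus chord distances; NaN where a locus is untyped.

    Pairs are in ``itertools.combinations`` order over population labels.
    """
    freqs = _freq_table(table)
    pops = table.population_labels
    n = len(pops)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    out = np.full((len(pairs), table.n_loci), np.nan)
    for pi, (i, j) in enumerate(pairs):
        for l in range(table.n_loci):
            x, y = freqs[i][l], freqs[j][l]
            if x is None or y is None:
                log.info("dce: locus %s untyped for pair (%s, %s); dropped",
                         table.loci[l], pops[i], pops[j])
                continue
            out[pi, l] = _dce_locus(x, y)
    return out


def dce_distance(table: GenotypeTable) -> DistanceMatrix:
    """Mean-over-loci Cavalli-Sforza & Edwards chord distance matrix."""
    pops = table.population_labels
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    per_locus = dce_per_locus(table)
    n = len(pops)
    m = np.zeros((n, n))
    pi = 0
    for i in range(n):
        for j in range(i + 1, n):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                d = np.nanmean(per_locus[pi])
            m[i, j] = m[j, i] = 0.0 if np.isnan(d) else d
            pi += 1
    return DistanceMatrix(labels=list(pops), values=m)


# ---------------------------------------------------------------------------
# Neighbor-joining with bootstrap supports
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.label] if self.label else []
        out: list[str] = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class TreeWithSupport:
    """Unrooted tree over population labels with optional bootstrap supports."""

    root: TreeNode
    labels: list[str]
    supports: dict[frozenset, float] | None = None  # bipartition -> percent

    def newick(self) -> str:
        def fmt(node: TreeNode, blen: float | None) -> str:
            if not node.children:
                s = node.label or ""
            else:
                inner = ",".join(fmt(c, b) for c, b in node.children)
                sup = "" if node.support is None else f"{node.support:.0f}"
                s = f"({inner}){sup}"
            return s if blen is None else f"{s}:{blen:.6f}"

        return fmt(self.root, None) + ";"

    def bipartitions(self) -> set[frozenset]:
        return _tree_bipartitions(self.root, set(self.labels))


def _tree_bipartitions(root: TreeNode, all_labels: set) -> set[frozenset]:
    """Non-trivial bipartitions, canonicalized as the side not holding min(label)."""
    ref = min(all_labels)
    out: set[frozenset] = set()

    def walk(node: TreeNode) -> set:
        if not node.children:
            return {node.label}
        below: set = set()
        for c, _ in node.children:
            below |= walk(c)
        if 2 <= len(below) <= len(all_labels) - 2:
            side = below if ref not in below else all_labels - below
            out.add(frozenset(side))
        return below

    walk(root)
    return out


def nj_tree(d: DistanceMatrix) -> TreeWithSupport:
    """Neighbor-joining with deterministic tie-breaking.

    Joins the pair with the smallest Q-value; ties are broken by the
    lexicographically smallest (label_i, label_j).  Negative branch lengths
    are clamped to zero with the deficit transferred to the sibling edge.
    """
    labels = list(d.labels)
    if len(labels) < 3:
        raise ValueError("neighbor-joining needs at least 3 labels")
    nodes: dict[str, TreeNode] = {l: TreeNode(label=l) for l in labels}
    key_of = {l: (l,) for l in labels}  # lexicographic tie-break key
    dist: dict[tuple[str, str], float] = {}
    act = list(labels)
    for i, a in enumerate(act):
        for b in act[i + 1:]:
            dist[(a, b)] = d.get(a, b)

    def D(a: str, b: str) -> float:
        return dist[(a, b)] if (a, b) in dist else dist[(b, a)]

    counter = 0
    while len(act) > 3:
        r = len(act)
        sums = {a: sum(D(a, b) for b in act if b != a) for a in act}
        best = None
        for i, a in enumerate(act):
            for b in act[i + 1:]:
                q = (r - 2) * D(a, b) - sums[a] - sums[b]
                cand_key = tuple(sorted((min(key_of[a], key_of[b]),
                                         max(key_of[a], key_of[b]))))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and cand_key < best[3]
                ):
                    best = (q, a, b, cand_key)
        _, a, b, _ = best
        dab = D(a, b)
        la = 0.5 * dab + (sums[a] - sums[b]) / (2 * (r - 2))
        lb = dab - la
        if la < 0:
            lb += -la
            la = 0.0
            log.info("nj: negative branch clamped at join of %s", a)
        if lb < 0:
            la += -lb
            lb = 0.0
            log.info("nj: negative branch clamped at join of %s", b)
        new = f"__internal{counter}"
        counter += 1
        nodes[new] = TreeNode(children=[(nodes[a], la), (nodes[b], lb)])
        key_of[new] = min(key_of[a], key_of[b])
        for c in act:
            if c in (a, b):
                continue
            dist[(new, c)] = 0.5 * (D(a, c) + D(b, c) - dab)
        act = [c for c in act if c not in (a, b)] + [new]

    # final three-point join
    a, b, c = sorted(act, key=lambda x: key_of[x])
    la = 0.5 * (D(a, b) + D(a, c) - D(b, c))
    lb = 0.5 * (D(a, b) + D(b, c) - D(a, c))
    lc = 0.5 * (D(a, c) + D(b, c) - D(a, b))
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    root = TreeNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return TreeWithSupport(root=root, labels=labels)


def bootstrap_tree(
    table: GenotypeTable,
    n_boot: int = 1000,
    seed: int = 0,
) -> TreeWithSupport:
    """NJ tree on D_CE with locus-bootstrap supports on the full-data topology."""
    if table.n_loci < 2:
        raise ValueError("bootstrap supports are undefined for a single-locus table")
    if len(table.population_labels) < 4:
        raise ValueError("need >= 4 populations for informative supports")
    pops = table.population_labels
    per_locus = dce_per_locus(table)  # (n_pairs, n_loci)
    n = len(pops)

    def matrix_from(cols: np.ndarray) -> DistanceMatrix:
        m = np.zeros((n, n))
        pi = 0
        for i in range(n):
            for j in range(i + 1, n):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    v = np.nanmean(per_locus[pi, cols])
                m[i, j] = m[j, i] = 0.0 if np.isnan(v) else v
                pi += 1
        return DistanceMatrix(labels=list(pops), values=m)

    full = nj_tree(matrix_from(np.arange(table.n_loci)))
    target = full.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        cols = rng.integers(0, table.n_loci, size=table.n_loci)
        rep = nj_tree(matrix_from(cols))
        rep_bps = rep.bipartitions()
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    supports = {bp: 100.0 * c / n_boot for bp, c in counts.items()}
    _annotate_supports(full.root, set(pops), supports)
    full.supports = supports
    return full


def _annotate_supports(root: TreeNode, all_labels: set, supports: dict) -> None:
    ref = min(all_labels)

    def walk(node: TreeNode) -> set:
        if not node.children:
            return {node.label}
        below: set = set()
        for c, _ in node.children:
            below |= walk(c)
        if 2 <= len(below) <= len(all_labels) - 2:
            side = below if ref not in below else all_labels - below
            node.support = supports.get(frozenset(side))
        return below

    walk(root)
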
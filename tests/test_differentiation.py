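"""F_ST, chord distance and neighbor-joining against independent oracles."""

import numpy as np
import pytest

from msatpop.differentiation import (
    DCE_LOCUS_MAX,
    DistanceMatrix,
    bootstrap_tree,
    dce_distance,
    fst,
    fst_permutation_p,
    nj_tree,
)
from msatpop.genotype_io import GenotypeTable
from msatpop.synthetic import generate_toy


def _table_from_genotypes(pop_genos: dict[str, list[list[tuple[int, int]]]]):
    """Build a table from {pop: [per-individual list of (a, b) per locus]}."""
    inds, pops, rows = [], [], []
    for pop, people in pop_genos.items():
        for i, person in enumerate(people):
            inds.append(f"{pop}_{i}")
            pops.append(pop)
            rows.append(person)
    n_loci = len(rows[0])
    return GenotypeTable(
        inds, [f"L{j}" for j in range(n_loci)], np.array(rows), pops
    )


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def wc_theta_oracle(table: GenotypeTable, pops: list[str]) -> float:
    """Literal step-by-step transcription of the variance-component formulas,
    organised differently from the implementation (loops over everything)."""
    num = den = 0.0
    r = len(pops)
    for j in range(table.n_loci):
        data = {}
        for pop in pops:
            g = table.genotypes(pop, j)
            if g.shape[0] > 0:
                data[pop] = g
        if len(data) < 2:
            continue
        rr = len(data)
        ns = {p: g.shape[0] for p, g in data.items()}
        nbar = sum(ns.values()) / rr
        nc = (rr * nbar - sum(n * n for n in ns.values()) / (rr * nbar)) / (rr - 1)
        alleles = sorted({int(x) for g in data.values() for x in g.ravel()})
        for al in alleles:
            p_i, h_i = {}, {}
            for pop, g in data.items():
                p_i[pop] = np.mean(g.ravel() == al)
                h_i[pop] = np.mean((g[:, 0] != g[:, 1]) & ((g[:, 0] == al) | (g[:, 1] == al)))
            pbar = sum(ns[p] * p_i[p] for p in data) / (rr * nbar)
            s2 = sum(ns[p] * (p_i[p] - pbar) ** 2 for p in data) / ((rr - 1) * nbar)
            hbar = sum(ns[p] * h_i[p] for p in data) / (rr * nbar)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (rr - 1) / rr * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (rr - 1) / rr * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            num += a
            den += a + b + c
    return num / den


def test_fst_matches_formula_transcription_oracle():
    table = generate_toy(n_pops=3, n_loci=6, n_ind=12, divergence_knob=0.4, seed=21)
    res = fst(table)
    assert res.global_theta == pytest.approx(wc_theta_oracle(table, table.population_labels), abs=1e-12)
    for a, b in [("pop1", "pop2"), ("pop1", "pop3"), ("pop2", "pop3")]:
        assert res.pairwise.get(a, b) == pytest.approx(wc_theta_oracle(table, [a, b]), abs=1e-12)


def test_fst_identical_and_fixed_extremes():
    # identical allele counts in both populations -> theta <= 0
    same = _table_from_genotypes(
        {
            "A": [[(10, 11)], [(10, 10)], [(11, 11)]],
            "B": [[(10, 11)], [(10, 10)], [(11, 11)]],
        }
    )
    assert fst(same, pairwise=False).global_theta <= 0
    # fixed for different alleles at every locus -> theta = 1
    fixed = _table_from_genotypes(
        {
            "A": [[(10, 10), (30, 30)]] * 4,
            "B": [[(20, 20), (40, 40)]] * 4,
        }
    )
    assert fst(fixed, pairwise=False).global_theta == pytest.approx(1.0)


def test_fst_pairwise_symmetry_and_global_in_locus_hull():
    table = generate_toy(n_pops=4, n_loci=8, n_ind=10, divergence_knob=0.6, seed=4)
    res = fst(table)
    assert np.allclose(res.pairwise.values, res.pairwise.values.T)
    per_locus = list(res.per_locus.values())
    assert min(per_locus) - 1e-9 <= res.global_theta <= max(per_locus) + 1e-9


def test_fst_permutation_identical_populations_near_one():
    rng = np.random.default_rng(0)
    geno = rng.integers(10, 14, size=(30, 4, 2))
    table = GenotypeTable(
        [f"i{k}" for k in range(60)],
        [f"L{j}" for j in range(4)],
        np.concatenate([geno, geno], axis=0),
        ["A"] * 30 + ["B"] * 30,
    )
    p = fst_permutation_p(table, ("A", "B"), n_perm=99, seed=1)
    assert p > 0.5


def test_fst_permutation_planted_divergence_minimal_p():
    table = generate_toy(n_pops=2, n_loci=8, n_ind=15, divergence_knob=4.0, seed=9)
    p = fst_permutation_p(table, ("pop1", "pop2"), n_perm=99, seed=2)
    assert p == pytest.approx(1 / 100)


# ---------------------------------------------------------------------------
# Chord distance
# ---------------------------------------------------------------------------

def test_dce_identical_and_disjoint():
    same = _table_from_genotypes(
        {"A": [[(10, 11)], [(10, 11)]], "B": [[(10, 11)], [(10, 11)]]}
    )
    assert dce_distance(same).get("A", "B") == pytest.approx(0.0)
    disjoint = _table_from_genotypes(
        {"A": [[(10, 10)], [(11, 11)]], "B": [[(20, 20)], [(21, 21)]]}
    )
    assert dce_distance(disjoint).get("A", "B") == pytest.approx(DCE_LOCUS_MAX)


def test_dce_matches_direct_summation_oracle():
    table = generate_toy(n_pops=3, n_loci=7, n_ind=12, divergence_knob=0.5, seed=31)
    got = dce_distance(table)
    pops = table.population_labels
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            per_locus = []
            for j in range(table.n_loci):
                fa = {}
                for x in table.genotypes(a, j).ravel():
                    fa[int(x)] = fa.get(int(x), 0) + 1
                fb = {}
                for x in table.genotypes(b, j).ravel():
                    fb[int(x)] = fb.get(int(x), 0) + 1
                na, nb = sum(fa.values()), sum(fb.values())
                s = sum(
                    np.sqrt(fa[al] / na * fb[al] / nb) for al in set(fa) & set(fb)
                )
                per_locus.append(2 / np.pi * np.sqrt(2 * max(0.0, 1 - s)))
            assert got.get(a, b) == pytest.approx(np.mean(per_locus), abs=1e-12)


def test_dce_bounds():
    table = generate_toy(n_pops=3, n_loci=5, n_ind=10, divergence_knob=1.0, seed=8)
    v = dce_distance(table).values
    assert np.all(v >= 0) and np.all(v <= DCE_LOCUS_MAX + 1e-12)


# ---------------------------------------------------------------------------
# Neighbor-joining
# ---------------------------------------------------------------------------

def test_nj_recovers_additive_tree():
    # ((A:1,B:2):1,(C:3,D:4)) pairwise path distances
    labels = ["A", "B", "C", "D"]
    d = np.array(
        [
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ],
        dtype=float,
    )
    tree = nj_tree(DistanceMatrix(labels, d))
    assert tree.bipartitions() == {frozenset({"C", "D"})}


def test_nj_three_taxa_closed_form():
    labels = ["A", "B", "C"]
    d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
    tree = nj_tree(DistanceMatrix(labels, d))
    lengths = {c.label: bl for c, bl in tree.root.children}
    assert lengths["A"] == pytest.approx(0.5 * (4 + 6 - 8))
    assert lengths["B"] == pytest.approx(0.5 * (4 + 8 - 6))
    assert lengths["C"] == pytest.approx(0.5 * (6 + 8 - 4))


def test_nj_rejects_asymmetric_input():
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [2.0, 0.0]]))


def test_nj_topology_matches_skbio():
    """Independent cross-check of the NJ agglomeration on a random matrix."""
    skbio = pytest.importorskip("skbio")
    table = generate_toy(n_pops=6, n_loci=8, n_ind=10, divergence_knob=0.8, seed=13)
    d = dce_distance(table)
    ours = nj_tree(d)
    dm = skbio.DistanceMatrix(d.values, ids=d.labels)
    theirs = skbio.tree.nj(dm)
    ref_bps = set()
    all_labels = set(d.labels)
    ref = min(all_labels)
    for node in theirs.non_tips():
        below = {t.name for t in node.tips()}
        if 2 <= len(below) <= len(all_labels) - 2:
            ref_bps.add(frozenset(below if ref not in below else all_labels - below))
    assert ours.bipartitions() == ref_bps


def test_nj_invariant_to_label_permutation():
    table = generate_toy(n_pops=5, n_loci=6, n_ind=10, divergence_knob=0.7, seed=17)
    d = dce_distance(table)
    perm = [3, 1, 4, 0, 2]
    d2 = DistanceMatrix(
        [d.labels[i] for i in perm], d.values[np.ix_(perm, perm)]
    )
    assert nj_tree(d).bipartitions() == nj_tree(d2).bipartitions()


# ---------------------------------------------------------------------------
# Bootstrap supports
# ---------------------------------------------------------------------------

def test_bootstrap_identical_loci_full_support():
    base = generate_toy(n_pops=5, n_loci=1, n_ind=10, divergence_knob=0.8, seed=19)
    copies = np.repeat(base.alleles, 4, axis=1)
    table = GenotypeTable(
        base.individuals, [f"L{j}" for j in range(4)], copies, base.populations
    )
    tree = bootstrap_tree(table, n_boot=50, seed=0)
    assert all(v == 100.0 for v in tree.supports.values())


def test_bootstrap_single_replicate_supports_are_binary():
    table = generate_toy(n_pops=5, n_loci=6, n_ind=10, divergence_knob=0.8, seed=23)
    tree = bootstrap_tree(table, n_boot=1, seed=3)
    assert set(tree.supports.values()) <= {0.0, 100.0}


def test_bootstrap_rejects_single_locus():
    table = generate_toy(n_pops=4, n_loci=1, n_ind=8, seed=1)
    with pytest.raises(ValueError, match="single-locus"):
        bootstrap_tree(table, n_boot=10)
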
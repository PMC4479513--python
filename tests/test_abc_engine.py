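"""ABC engine: priors, summary statistics, scenario choice, posteriors."""

import numpy as np
import pandas as pd
import pytest

from msatpop.abc_engine import (
    PosteriorSummary,
    PriorSpec,
    ReferenceTable,
    ScenarioSpec,
    build_reference_table,
    choose_scenario,
    draw_parameters,
    estimate_posteriors,
    generations_to_years,
    model_check,
    percent_size_change,
    summary_stats,
)
from msatpop.bottleneck import m_ratio
from msatpop.differentiation import fst
from msatpop.diversity import heterozygosities
from msatpop.genotype_io import GenotypeTable, PopulationGroup
from msatpop.scenarios import (
    DEFAULT_MUTATION_MODEL,
    GROUPS,
    build_common_ancestor_scenario,
    build_winning_scenario,
    common_ancestor_prior,
    winning_prior,
)
from msatpop.synthetic import generate_toy


class TestPriors:
    def test_uniform_moment(self):
        prior = PriorSpec(bounds={"x": (10.0, 10_000.0)})
        rng = np.random.default_rng(1)
        draws = np.array([draw_parameters(prior, rng)["x"] for _ in range(20_000)])
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - 5005.0) < 3 * se

    def test_ordering_constraint_halves_acceptance(self):
        prior = PriorSpec(bounds={"t1": (0.0, 1.0), "t2": (0.0, 1.0)},
                          constraints=[("t2", "t1")])
        rng = np.random.default_rng(2)
        draws = [draw_parameters(prior, rng) for _ in range(5000)]
        assert all(d["t2"] > d["t1"] for d in draws)

    def test_three_ordered_times_rank_uniform_on_simplex(self):
        """Conditioned on the full ordering, each of the 3! rank patterns of
        fresh unconstrained draws is equally likely — so constrained draws
        are uniform on the order simplex.  Check via marginal quantiles."""
        prior = PriorSpec(
            bounds={"a": (0.0, 1.0), "b": (0.0, 1.0), "c": (0.0, 1.0)},
            constraints=[("b", "a"), ("c", "b")],
        )
        rng = np.random.default_rng(3)
        draws = pd.DataFrame([draw_parameters(prior, rng) for _ in range(8000)])
        # order statistics of 3 uniforms: means 1/4, 1/2, 3/4
        for name, expect in [("a", 0.25), ("b", 0.5), ("c", 0.75)]:
            se = draws[name].std() / np.sqrt(len(draws))
            assert abs(draws[name].mean() - expect) < 4 * se

    def test_unsatisfiable_constraints_abort(self):
        prior = PriorSpec(bounds={"a": (0.0, 1.0), "b": (5.0, 6.0)},
                          constraints=[("a", "b")])
        with pytest.raises(RuntimeError, match="acceptance"):
            draw_parameters(prior, 4, max_attempts=2000)


class TestSummaryStats:
    def test_cross_module_consistency(self):
        """Each statistic equals its module-of-origin computation on the
        pooled group table."""
        table = generate_toy(n_pops=4, n_loci=6, n_ind=10, divergence_knob=0.5, seed=41)
        g1 = PopulationGroup("g1", ["pop1", "pop2"])
        g2 = PopulationGroup("g2", ["pop3", "pop4"])
        stats = summary_stats(table, [g1, g2])

        def pooled(group, label):
            sub = table.subset_populations(group.members)
            return GenotypeTable(
                sub.individuals, sub.loci, sub.alleles, [label] * sub.n_individuals
            )

        p1, p2 = pooled(g1, "g1"), pooled(g2, "g2")
        assert stats["gd_g1"] == pytest.approx(heterozygosities(p1).loc["g1", "H_E"])
        assert stats["m_g2"] == pytest.approx(m_ratio(p2, "g2").mean)
        both = GenotypeTable(
            p1.individuals + p2.individuals,
            p1.loci,
            np.concatenate([p1.alleles, p2.alleles]),
            ["g1"] * p1.n_individuals + ["g2"] * p2.n_individuals,
        )
        assert stats["fst_g1_g2"] == pytest.approx(
            fst(both, pairwise=False).global_theta
        )
        mean_k = np.mean(
            [len(p1.allele_counts("g1", j)[0]) for j in range(p1.n_loci)]
        )
        assert stats["na_g1"] == pytest.approx(mean_k)

    def test_monomorphic_dataset_degenerate_values(self):
        alleles = np.full((8, 3, 2), 12)
        table = GenotypeTable(
            [f"i{k}" for k in range(8)],
            ["L1", "L2", "L3"],
            alleles,
            ["A"] * 4 + ["B"] * 4,
        )
        ga, gb = PopulationGroup("A", ["A"]), PopulationGroup("B", ["B"])
        stats = summary_stats(table, [ga, gb])
        assert stats["na_A"] == 1.0
        assert stats["gd_A"] == 0.0
        assert stats["m_A"] == 1.0
        assert stats["fst_A_B"] == 0.0

    def test_identical_groups_symmetric(self):
        table = generate_toy(n_pops=2, n_loci=5, n_ind=12, divergence_knob=0.0, seed=6)
        ga = PopulationGroup("A", ["pop1"])
        gb = PopulationGroup("B", ["pop2"])
        stats = summary_stats(table, [ga, gb])
        assert stats["fst_A_B"] <= 0.05  # exchangeable populations


def _gaussian_reference(seed: int, n: int = 400, sep: float = 3.0) -> ReferenceTable:
    """Synthetic reference table: two scenarios as shifted Gaussian clouds."""
    rng = np.random.default_rng(seed)
    stats_a = rng.normal(0.0, 1.0, size=(n, 4))
    stats_b = rng.normal(sep, 1.0, size=(n, 4))
    params = rng.uniform(10, 100, size=(2 * n, 2))
    prior = PriorSpec(bounds={"p0": (10.0, 100.0), "p1": (10.0, 100.0)})
    return ReferenceTable(
        scenario_ids=np.array(["A"] * n + ["B"] * n),
        params=pd.DataFrame(params, columns=["p0", "p1"]),
        stats=pd.DataFrame(np.vstack([stats_a, stats_b]),
                           columns=[f"gd_{i}" for i in range(4)]),
        priors={"A": prior, "B": prior},
    )


class TestChooseScenario:
    def test_local_dominance_of_matching_scenario(self):
        ref = _gaussian_reference(1)
        obs = ref.stats.iloc[3]  # a scenario-A row
        probs = choose_scenario(ref, obs, retain_fraction=0.2)
        assert probs["A"] > 0.5
        assert sum(probs.values()) == pytest.approx(1.0)

    def test_identical_generating_processes_near_half(self):
        vals = []
        for seed in range(12):
            ref = _gaussian_reference(seed, n=300, sep=0.0)
            obs = pd.Series(np.zeros(4), index=ref.stats.columns)
            probs = choose_scenario(ref, obs, retain_fraction=0.2)
            vals.append(probs["A"])
        assert abs(np.mean(vals) - 0.5) < 0.1

    def test_absent_scenario_gets_zero_with_warning(self):
        ref = _gaussian_reference(2, sep=30.0)
        obs = pd.Series(np.zeros(4) - 1.0, index=ref.stats.columns)
        with pytest.warns(UserWarning, match="probability 0"):
            probs = choose_scenario(ref, obs, retain_fraction=0.05)
        assert probs["B"] == 0.0 and probs["A"] == 1.0

    def test_rescaling_invariance(self):
        """MAD normalization absorbs units: scaling one statistic does not
        change the probabilities."""
        ref = _gaussian_reference(3)
        obs = ref.stats.iloc[10]
        p1 = choose_scenario(ref, obs, retain_fraction=0.2)
        scaled = ReferenceTable(
            scenario_ids=ref.scenario_ids,
            params=ref.params,
            stats=ref.stats * pd.Series(
                {c: (100.0 if i == 0 else 1.0) for i, c in enumerate(ref.stats.columns)}
            ),
            priors=ref.priors,
        )
        obs2 = obs * pd.Series(
            {c: (100.0 if i == 0 else 1.0) for i, c in enumerate(ref.stats.columns)}
        )
        p2 = choose_scenario(scaled, obs2, retain_fraction=0.2)
        assert p1["A"] == pytest.approx(p2["A"], abs=1e-9)


class TestEstimatePosteriors:
    def _linear_reference(self, seed: int, n: int = 2000) -> ReferenceTable:
        """Parameters linearly encoded in noisy stats (identifiable case)."""
        rng = np.random.default_rng(seed)
        p0 = rng.uniform(10, 100, n)
        p1 = rng.uniform(10, 100, n)
        stats = np.column_stack(
            [p0 + rng.normal(0, 2, n), p1 + rng.normal(0, 2, n),
             p0 - p1 + rng.normal(0, 2, n)]
        )
        prior = PriorSpec(bounds={"p0": (10.0, 100.0), "p1": (10.0, 100.0)})
        return ReferenceTable(
            scenario_ids=np.array(["A"] * n),
            params=pd.DataFrame({"p0": p0, "p1": p1}),
            stats=pd.DataFrame(stats, columns=["s0", "s1", "s2"]),
            priors={"A": prior},
        )

    def test_recovers_known_parameters(self):
        ref = self._linear_reference(1)
        obs = pd.Series({"s0": 40.0, "s1": 70.0, "s2": -30.0})
        post = estimate_posteriors(ref, "A", obs, retain_fraction=0.2)
        lo, med, hi = post.interval("p0")
        assert lo <= 40.0 <= hi and abs(med - 40.0) < 5.0
        lo, med, hi = post.interval("p1")
        assert lo <= 70.0 <= hi and abs(med - 70.0) < 5.0

    def test_intervals_honour_prior_bounds(self):
        ref = self._linear_reference(2)
        # observed far outside the simulated cloud pushes the adjustment hard
        obs = pd.Series({"s0": 150.0, "s1": -20.0, "s2": 160.0})
        post = estimate_posteriors(ref, "A", obs, retain_fraction=0.2)
        for p in ("p0", "p1"):
            lo, med, hi = post.interval(p)
            assert 10.0 <= lo <= med <= hi <= 100.0

    def test_centered_observed_leaves_medians_unadjusted(self):
        ref = self._linear_reference(3)
        keepers = ref.stats.median()
        post = estimate_posteriors(ref, "A", pd.Series(keepers), retain_fraction=0.2)
        mask = np.ones(len(ref.stats), dtype=bool)
        # rejection-only posterior of the same retained set
        from msatpop.abc_engine import _retained_indices

        keep, _, _ = _retained_indices(ref, pd.Series(keepers), 0.2)
        for p in ("p0", "p1"):
            raw_med = np.median(ref.params[p].to_numpy()[keep])
            assert abs(post.interval(p)[1] - raw_med) < 3.0

    def test_too_few_retained_rejected(self):
        ref = self._linear_reference(4, n=100)
        with pytest.raises(ValueError, match="retained"):
            estimate_posteriors(ref, "A", ref.stats.iloc[0], retain_fraction=0.05)


class TestModelCheck:
    def test_simulated_row_inside_bands(self):
        ref = _gaussian_reference(5)
        rep = model_check(ref, ref.stats.iloc[7])
        assert rep["all_inside"]

    def test_distant_observed_flagged_outside(self):
        ref = _gaussian_reference(6)
        obs = ref.stats.iloc[7] + 10.0 * ref.mad_scale()
        rep = model_check(ref, obs)
        assert not rep["all_inside"]


class TestReportingArithmetic:
    @pytest.mark.parametrize(
        "post, pre, expected",
        [(3270.0, 4950.0, -34), (1400.0, 4570.0, -69), (5640.0, 5430.0, 4)],
    )
    def test_percent_size_change_worked_examples(self, post, pre, expected):
        assert percent_size_change(post, pre) == expected

    def test_percent_size_change_rejects_nonpositive_pre(self):
        with pytest.raises(ValueError):
            percent_size_change(100.0, 0.0)

    @pytest.mark.parametrize(
        "gens, years", [(240.0, 960.0), (38.9, 155.6), (0.0, 0.0)]
    )
    def test_generations_to_years(self, gens, years):
        ybp, calendar = generations_to_years(gens, generation_time=4.0, present_year=2010)
        assert ybp == pytest.approx(years)
        assert calendar == pytest.approx(2010 - years)


class TestReferenceTable:
    def test_row_counts_and_reproducibility(self):
        sizes = {g: 3 for g in GROUPS}
        groups = [PopulationGroup(g, [g]) for g in GROUPS]
        specs = [
            ScenarioSpec("win", winning_prior(),
                         lambda p: build_winning_scenario(p, sizes)),
            ScenarioSpec("alt", common_ancestor_prior(),
                         lambda p: build_common_ancestor_scenario(p, sizes)),
        ]
        r1 = build_reference_table(specs, DEFAULT_MUTATION_MODEL, 2, 99, groups, n_loci=3)
        r2 = build_reference_table(specs, DEFAULT_MUTATION_MODEL, 2, 99, groups, n_loci=3)
        assert r1.n_rows == 4
        assert list(r1.scenario_ids) == ["win", "win", "alt", "alt"]
        pd.testing.assert_frame_equal(r1.stats, r2.stats)
        pd.testing.assert_frame_equal(r1.params, r2.params)

    def test_tsv_round_trip(self, tmp_path):
        ref = _gaussian_reference(9, n=20)
        ref.to_tsv(tmp_path / "ref.tsv")
        df = pd.read_csv(tmp_path / "ref.tsv", sep="\t")
        assert len(df) == 40
        assert "scenario" in df.columns
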
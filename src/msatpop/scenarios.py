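"""Packaged demographic scenarios for the mining-impacted trout system.

Five population groups are modelled: a general clean lineage and four
metal-impacted lineages (Red River; Crowlas/Trevaylor; downstream Hayle;
upstream Hayle).  The selected ("winning") hypothesis has each metal lineage
derived independently from the clean lineage at a single clean-metal split
time ``t2``, with the within-Hayle split at ``t1 < t2``; each metal lineage
carries a bottleneck: looking backwards, size ``N`` on ``[0, db)`` and the
pre-bottleneck ``N2`` on ``[db, t2)``.  The alternative hypothesis derives
clean and metal lineages from an unsampled common ancestor at ``t2`` with no
bottlenecks.

Scenario builders take a parameter dictionary (generations / diploid sizes)
and diploid sample sizes per deme, and return a concrete
:class:`~msatpop.coalescent.Scenario`.  ``POSTERIOR_MEDIANS`` holds the
point estimates used as generator defaults by the synthetic-data module.
"""

from __future__ import annotations

from typing import Mapping

from .abc_engine import PriorSpec
from .coalescent import Deme, MergeEvent, MutationModel, Scenario

__all__ = [
    "GROUPS",
    "POSTERIOR_MEDIANS",
    "DEFAULT_MUTATION_MODEL",
    "build_winning_scenario",
    "build_common_ancestor_scenario",
    "winning_prior",
    "common_ancestor_prior",
]

#: Deme (population-group) names used by the packaged scenarios.
GROUPS = ("clean", "redriver", "crowlastrevaylor", "hayledown", "hayleup")

#: Posterior point estimates (medians) for the selected scenario, in
#: generations / diploid effective sizes; the synthetic-data defaults.
POSTERIOR_MEDIANS: dict[str, float] = {
    "N_clean": 9220.0,
    "N_redriver": 3270.0,
    "N_crowlastrevaylor": 5640.0,
    "N_hayledown": 1400.0,
    "N_hayleup": 2900.0,
    "t1": 38.9,
    "t2": 240.0,
    "db_redriver": 165.0,
    "N2_redriver": 4950.0,
    "db_crowlastrevaylor": 159.0,
    "N2_crowlastrevaylor": 5430.0,
    "db_hayle": 180.0,
    "N2_hayle": 4570.0,
    "mu_mean": 5.34e-4,
}

#: Microsatellite mutation model with the default rate prior mean.
DEFAULT_MUTATION_MODEL = MutationModel(
    mean_rate=5e-4, rate_shape=2.0, p_single=0.78, multi_step_mean=3.1,
    state_bounds=(10, 49),
)

#: Years per generation used to convert coalescent times to calendar dates.
GENERATION_TIME_YEARS = 4.0


def _eps(t: float) -> float:
    return max(1e-6, 1e-9 * t)


def build_winning_scenario(
    params: Mapping[str, float],
    sample_sizes: Mapping[str, int],
) -> Scenario:
    """Metal lineages independently derived from the clean lineage at ``t2``.

    ``sample_sizes`` maps a subset of :data:`GROUPS` to diploid counts.
    Required parameters: per-group N, ``t1``, ``t2``, per-metal-lineage
    ``db`` and ``N2`` (the Hayle shares one bottleneck).
    """
    p = dict(params)
    t1, t2 = p["t1"], p["t2"]
    if not t2 > t1:
        raise ValueError(f"constraint t2 > t1 violated (t1={t1}, t2={t2})")

    def bottleneck_epochs(n_now: float, db: float, n_pre: float, t_end: float):
        db = min(db, t_end - _eps(t_end))  # size change must precede the merge
        return ((0.0, n_now), (db, n_pre))

    demes = [Deme("clean", ((0.0, p["N_clean"]),))]
    for grp in ("redriver", "crowlastrevaylor"):
        demes.append(
            Deme(grp, bottleneck_epochs(p[f"N_{grp}"], p[f"db_{grp}"], p[f"N2_{grp}"], t2))
        )
    db_h = p["db_hayle"]
    if db_h > t1:
        # bottleneck recovery happens on the merged Hayle lineage: the
        # ancestor runs at the upstream size on [t1, db) then N2 to t2
        demes.append(Deme("hayledown", ((0.0, p["N_hayledown"]),)))
        demes.append(Deme("hayleup", ((0.0, p["N_hayleup"]),)))
        hayle_anc = Deme(
            "hayle_anc", ((0.0, p["N_hayleup"]), (min(db_h, t2 - _eps(t2)), p["N2_hayle"]))
        )
    else:
        # the size change predates the within-Hayle split: both daughters
        # revert to N2 at db and the ancestor runs at N2 throughout
        demes.append(Deme("hayledown", ((0.0, p["N_hayledown"]), (db_h, p["N2_hayle"]))))
        demes.append(Deme("hayleup", ((0.0, p["N_hayleup"]), (db_h, p["N2_hayle"]))))
        hayle_anc = Deme("hayle_anc", ((0.0, p["N2_hayle"]),))
    demes.append(hayle_anc)

    events = [
        MergeEvent(t1, ("hayledown", "hayleup"), "hayle_anc"),
        MergeEvent(t2, ("redriver",), "clean"),
        MergeEvent(t2, ("crowlastrevaylor",), "clean"),
        MergeEvent(t2, ("hayle_anc",), "clean"),
    ]
    samples = tuple((g, int(sample_sizes[g])) for g in GROUPS if g in sample_sizes)
    return Scenario(demes=tuple(demes), events=tuple(events), sample_sizes=samples)


def build_common_ancestor_scenario(
    params: Mapping[str, float],
    sample_sizes: Mapping[str, int],
) -> Scenario:
    """Every lineage independently derived from an unsampled common ancestor.

    All five group lineages — including the two Hayle lineages, which are
    *not* nested here — merge into an ancestor of size ``N_ancestor`` at
    ``t2``.  No bottleneck epochs.  This is the structurally distinct
    alternative to the selected hypothesis: it has no recent within-Hayle
    coalescence and no metal-lineage size reductions.
    """
    p = dict(params)
    t2 = p["t2"]
    demes = [Deme(g, ((0.0, p[f"N_{g}"]),)) for g in GROUPS]
    demes.append(Deme("ancestor", ((0.0, p["N_ancestor"]),)))
    events = [
        MergeEvent(t2, ("clean", "redriver"), "ancestor"),
        MergeEvent(t2, ("crowlastrevaylor",), "ancestor"),
        MergeEvent(t2, ("hayledown", "hayleup"), "ancestor"),
    ]
    samples = tuple((g, int(sample_sizes[g])) for g in GROUPS if g in sample_sizes)
    return Scenario(demes=tuple(demes), events=tuple(events), sample_sizes=samples)


def winning_prior() -> PriorSpec:
    """Priors for the selected scenario: sizes U(10, 10000); t1 capped at
    3000 generations; bottleneck duration capped at 300; t2 > t1, t2 > db."""
    bounds = {f"N_{g}": (10.0, 10000.0) for g in GROUPS}
    bounds.update(
        {
            "t1": (10.0, 3000.0),
            "t2": (10.0, 10000.0),
            "db_redriver": (10.0, 300.0),
            "N2_redriver": (10.0, 10000.0),
            "db_crowlastrevaylor": (10.0, 300.0),
            "N2_crowlastrevaylor": (10.0, 10000.0),
            "db_hayle": (10.0, 300.0),
            "N2_hayle": (10.0, 10000.0),
            "mu_mean": (1e-4, 1e-3),
        }
    )
    constraints = [
        ("t2", "t1"),
        ("t2", "db_redriver"),
        ("t2", "db_crowlastrevaylor"),
        ("t2", "db_hayle"),
    ]
    return PriorSpec(bounds=bounds, constraints=constraints)


def common_ancestor_prior() -> PriorSpec:
    bounds = {f"N_{g}": (10.0, 10000.0) for g in GROUPS}
    bounds.update(
        {
            "N_ancestor": (10.0, 10000.0),
            "t2": (10.0, 10000.0),
            "mu_mean": (1e-4, 1e-3),
        }
    )
    return PriorSpec(bounds=bounds, constraints=[])
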
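"""Approximate Bayesian computation for microsatellite demographies.

Workflow: draw parameters from constrained uniform priors, simulate datasets
under candidate demographic scenarios, reduce each to a fixed vector of
summary statistics, and store the (scenario, parameters, statistics) rows in
a reference table.  An observed dataset is then analysed by

* **scenario choice** — retain the simulations closest to the observed
  statistics (Euclidean distance on MAD-normalized stats) and fit a
  multinomial logistic regression of scenario identity on the statistics,
  evaluated at the observed point;
* **parameter estimation** — local-linear regression adjustment of the
  retained parameter draws (logit-transformed to their prior range) on the
  statistic discrepancies, summarised by the median and an equal-tailed 95%
  interval;
* **model checking** — principal-component projection of the observed
  statistics against the simulated cloud with per-component percentile bands.

Summary statistics per population group: mean number of alleles, mean genic
diversity, mean M; per group pair: Weir-Cockerham F_ST and a mean genotype
classification index; optionally mean allele-size variance for model checks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression

from .coalescent import MutationModel, Scenario, simulate_dataset
from .differentiation import _locus_components
from .genotype_io import GenotypeTable, PopulationGroup

__all__ = [
    "PriorSpec",
    "ScenarioSpec",
    "ReferenceTable",
    "PosteriorSummary",
    "draw_parameters",
    "summary_stats",
    "build_reference_table",
    "choose_scenario",
    "estimate_posteriors",
    "model_check",
    "percent_size_change",
    "generations_to_years",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors with strict ordering constraints.

    ``bounds`` maps parameter -> (min, max); ``constraints`` is a list of
    ``(greater, lesser)`` parameter-name pairs enforced by rejection.
    """

    bounds: Mapping[str, tuple[float, float]]
    constraints: Sequence[tuple[str, str]] = ()

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"prior for {name!r} needs min < max")
        for a, b in self.constraints:
            if a not in self.bounds or b not in self.bounds:
                raise ValueError(f"constraint ({a} > {b}) references unknown parameter")

    def satisfies(self, params: Mapping[str, float]) -> bool:
        return all(params[a] > params[b] for a, b in self.constraints)


def draw_parameters(
    prior: PriorSpec,
    rng: np.random.Generator | int,
    max_attempts: int = 10000,
) -> dict[str, float]:
    """One constrained draw; aborts if the acceptance rate falls below 1e-4."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    names = list(prior.bounds)
    for _ in range(max_attempts):
        draw = {
            n: float(rng.uniform(lo, hi)) for n, (lo, hi) in prior.bounds.items()
        }
        if prior.satisfies(draw):
            return draw
    raise RuntimeError(
        f"prior constraint acceptance below {1.0 / max_attempts:g}; "
        f"constraints {list(prior.constraints)} may be nearly unsatisfiable"
    )


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def _group_locus_summaries(table: GenotypeTable, group: PopulationGroup):
    """Per-locus (freqs, het, n, genotypes) with the group's populations pooled."""
    idx = np.concatenate([table.pop_indices(p) for p in group.members])
    out = []
    for j in range(table.n_loci):
        geno = table.alleles[idx, j, :]
        geno = geno[geno[:, 0] != 0]
        n = geno.shape[0]
        if n == 0:
            out.append(None)
            continue
        copies = geno.ravel()
        states, counts = np.unique(copies, return_counts=True)
        freqs = {int(s): c / copies.size for s, c in zip(states, counts)}
        is_het = geno[:, 0] != geno[:, 1]
        het = {
            int(s): float(np.sum(is_het & ((geno[:, 0] == s) | (geno[:, 1] == s)))) / n
            for s in states
        }
        out.append((freqs, het, n, geno))
    return out


def _classification_index(
    geno_i: list, summaries_j: list, n_loci: int
) -> float:
    """Mean over group-i individuals of log10 multilocus genotype likelihood
    under group-j allele frequencies (pseudo-count 1/(2n+1) for unseen alleles)."""
    total = 0.0
    count = 0
    per_ind: dict[int, float] = {}
    for l in range(n_loci):
        si, sj = geno_i[l], summaries_j[l]
        if si is None or sj is None:
            continue
        freqs_j, _, n_j, _ = sj
        pseudo = 1.0 / (2 * n_j + 1)
        geno = si[3]
        a = geno[:, 0]
        b = geno[:, 1]
        pa = np.array([freqs_j.get(int(x), pseudo) for x in a])
        pb = np.array([freqs_j.get(int(x), pseudo) for x in b])
        lik = pa * pb * np.where(a != b, 2.0, 1.0)
        contrib = np.log10(lik)
        for ind, v in enumerate(contrib):
            per_ind[ind] = per_ind.get(ind, 0.0) + float(v)
    if not per_ind:
        return 0.0
    return float(np.mean(list(per_ind.values())))


def summary_stats(
    table: GenotypeTable,
    groups: Sequence[PopulationGroup],
    include_size_variance: bool = False,
) -> pd.Series:
    """Fixed-order named summary-statistic vector for ABC.

    One-sample statistics pool each group's populations; two-sample
    statistics are computed for each unordered group pair.
    """
    for g in groups:
        g.validate_against(table)
        if not g.members:
            raise ValueError(f"group {g.name!r} is empty")
    summaries = {g.name: _group_locus_summaries(table, g) for g in groups}
    stats: dict[str, float] = {}
    for g in groups:
        s = summaries[g.name]
        na, gd, mm, va = [], [], [], []
        for entry in s:
            if entry is None:
                continue
            freqs, _, n, _ = entry
            states = np.array(list(freqs))
            p = np.array(list(freqs.values()))
            na.append(len(freqs))
            gd.append(1.0 - float(np.sum(p**2)))
            if len(freqs) == 1:
                mm.append(1.0)
            else:
                mm.append(len(freqs) / (int(states.max() - states.min()) + 1))
            mean = float(np.sum(p * states))
            va.append(float(np.sum(p * states**2) - mean**2))
        stats[f"na_{g.name}"] = float(np.mean(na))
        stats[f"gd_{g.name}"] = float(np.mean(gd))
        stats[f"m_{g.name}"] = float(np.mean(mm))
        if include_size_variance:
            stats[f"va_{g.name}"] = float(np.mean(va))
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            gi, gj = groups[i].name, groups[j].name
            si, sj = summaries[gi], summaries[gj]
            num = den = 0.0
            for l in range(table.n_loci):
                if si[l] is None or sj[l] is None:
                    continue
                a, abc = _locus_components(
                    [si[l][0], sj[l][0]], [si[l][1], sj[l][1]], [si[l][2], sj[l][2]]
                )
                num += a
                den += abc
            stats[f"fst_{gi}_{gj}"] = float(num / den) if den != 0 else 0.0
            ci = 0.5 * (
                _classification_index(si, sj, table.n_loci)
                + _classification_index(sj, si, table.n_loci)
            )
            stats[f"ci_{gi}_{gj}"] = ci
    return pd.Series(stats)


# ---------------------------------------------------------------------------
# Reference table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioSpec:
    """A named candidate scenario: prior + builder from a parameter draw."""

    name: str
    prior: PriorSpec
    build: Callable[[Mapping[str, float]], Scenario]


@dataclass
class ReferenceTable:
    """Simulated parameter draws paired with summary-statistic vectors."""

    scenario_ids: np.ndarray        # (n_rows,) of str
    params: pd.DataFrame            # NaN for parameters absent from a scenario
    stats: pd.DataFrame
    priors: dict[str, PriorSpec]

    @property
    def n_rows(self) -> int:
        return len(self.scenario_ids)

    def mad_scale(self) -> pd.Series:
        """Per-statistic median absolute deviation (robust normalization)."""
        med = self.stats.median(axis=0)
        mad = (self.stats - med).abs().median(axis=0)
        return mad

    def normalized(self) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
        mad = self.mad_scale()
        keep = mad > 0
        dropped = [c for c in self.stats.columns if not keep[c]]
        if dropped:
            log.warning("constant summary statistics dropped: %s", dropped)
        cols = self.stats.columns[keep]
        return self.stats[cols] / mad[cols], mad[cols], cols

    def to_tsv(self, path) -> None:
        df = pd.concat(
            [pd.Series(self.scenario_ids, name="scenario"), self.params, self.stats],
            axis=1,
        )
        df.to_csv(path, sep="\t", index=False)


def build_reference_table(
    scenarios: Sequence[ScenarioSpec],
    model: MutationModel,
    n_per_scenario: int,
    master_seed: int,
    groups: Sequence[PopulationGroup],
    n_loci: int = 23,
    include_size_variance: bool = False,
) -> ReferenceTable:
    """Simulate ``n_per_scenario`` rows per scenario; deterministic given seed.

    The per-locus mean mutation rate ``mu_mean`` is drawn from each
    scenario's prior (it must appear in the prior bounds) and replaces the
    model's mean rate for that row.
    """
    if len(scenarios) < 1:
        raise ValueError("need at least one scenario")
    ss = np.random.SeedSequence(master_seed)
    rows_params: list[dict[str, float]] = []
    rows_stats: list[pd.Series] = []
    ids: list[str] = []
    for spec in scenarios:
        child = np.random.default_rng(ss.spawn(1)[0])
        for r in range(n_per_scenario):
            draw = draw_parameters(spec.prior, child)
            row_model = MutationModel(
                mean_rate=draw.get("mu_mean", model.mean_rate),
                rate_shape=model.rate_shape,
                p_single=model.p_single,
                multi_step_mean=model.multi_step_mean,
                state_bounds=model.state_bounds,
            )
            scenario = spec.build(draw)
            seed = int(child.integers(0, 2**31 - 1))
            try:
                table = simulate_dataset(scenario, row_model, n_loci, seed)
                stats = summary_stats(table, groups, include_size_variance)
            except Exception as exc:  # pragma: no cover - row context for debugging
                raise RuntimeError(
                    f"simulation failed for scenario {spec.name!r} row {r}: {exc}"
                ) from exc
            ids.append(spec.name)
            rows_params.append(draw)
            rows_stats.append(stats)
    return ReferenceTable(
        scenario_ids=np.array(ids),
        params=pd.DataFrame(rows_params),
        stats=pd.DataFrame(rows_stats),
        priors={s.name: s.prior for s in scenarios},
    )


# ---------------------------------------------------------------------------
# Scenario choice
# ---------------------------------------------------------------------------

def _retained_indices(
    ref: ReferenceTable, observed: pd.Series, retain_fraction: float
) -> tuple[np.ndarray, pd.DataFrame, pd.Series]:
    norm_stats, mad, cols = ref.normalized()
    obs = observed[cols] / mad
    dist = np.sqrt(((norm_stats - obs) ** 2).sum(axis=1).to_numpy())
    n_keep = max(2, int(round(retain_fraction * ref.n_rows)))
    keep = np.argsort(dist, kind="stable")[:n_keep]
    return keep, norm_stats, obs


def choose_scenario(
    ref: ReferenceTable,
    observed: pd.Series,
    retain_fraction: float = 0.01,
) -> dict[str, float]:
    """Posterior scenario probabilities via rejection + logistic regression."""
    if not (0.0 < retain_fraction <= 0.2):
        raise ValueError("retain_fraction must lie in (0, 0.2]")
    keep, norm_stats, obs = _retained_indices(ref, observed, retain_fraction)
    y = ref.scenario_ids[keep]
    names = sorted(set(ref.scenario_ids))
    present = sorted(set(y))
    missing = sorted(set(names) - set(present))
    if missing:
        warnings.warn(
            f"scenarios absent from the retained set get probability 0: {missing}",
            stacklevel=2,
        )
    if len(present) == 1:
        probs = {n: 0.0 for n in names}
        probs[present[0]] = 1.0
        return probs
    X = norm_stats.iloc[keep].to_numpy()
    centre = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - centre) / scale
    clf = LogisticRegression(max_iter=2000, C=1.0)  # ridge-stabilized
    clf.fit(Xs, y)
    xo = ((obs.to_numpy() - centre) / scale).reshape(1, -1)
    p = clf.predict_proba(xo)[0]
    probs = {n: 0.0 for n in names}
    for cls, pi in zip(clf.classes_, p):
        probs[str(cls)] = float(pi)
    return probs


# ---------------------------------------------------------------------------
# Parameter posteriors
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSummary:
    """Per-parameter equal-tailed 95% interval and median, plus adjusted draws."""

    scenario: str
    table: pd.DataFrame  # index: parameter; columns: q2.5, median, q97.5
    n_retained: int
    adjusted: pd.DataFrame = field(repr=False, default=None)

    def interval(self, param: str) -> tuple[float, float, float]:
        row = self.table.loc[param]
        return float(row["q2.5"]), float(row["median"]), float(row["q97.5"])


def estimate_posteriors(
    ref: ReferenceTable,
    scenario: str,
    observed: pd.Series,
    retain_fraction: float = 0.01,
    min_retained: int = 200,
) -> PosteriorSummary:
    """Local-linear regression-adjusted posterior for one scenario's parameters.

    Retained draws are logit-transformed onto their prior range before the
    adjustment and back-transformed afterwards, so the adjusted draws (and
    hence the intervals) always honour the prior bounds.
    """
    mask = ref.scenario_ids == scenario
    if not mask.any():
        raise KeyError(f"scenario {scenario!r} not in reference table")
    sub = ReferenceTable(
        scenario_ids=ref.scenario_ids[mask],
        params=ref.params.loc[mask].reset_index(drop=True),
        stats=ref.stats.loc[mask].reset_index(drop=True),
        priors=ref.priors,
    )
    keep, norm_stats, obs = _retained_indices(sub, observed, retain_fraction)
    if len(keep) < min_retained:
        raise ValueError(
            f"only {len(keep)} rows retained; need >= {min_retained} "
            "(increase retain_fraction or the reference table size)"
        )
    X = norm_stats.iloc[keep].to_numpy() - obs.to_numpy()
    prior = ref.priors[scenario]
    params = [c for c in sub.params.columns if sub.params[c].notna().all()]
    eps = 1e-9
    rows = {}
    adj_cols = {}
    design = np.column_stack([np.ones(len(keep)), X])
    for name in params:
        lo, hi = prior.bounds[name]
        x = sub.params[name].to_numpy()[keep]
        u = np.clip((x - lo) / (hi - lo), eps, 1 - eps)
        z = logit(u)
        try:
            beta, *_ = np.linalg.lstsq(design, z, rcond=None)
            z_adj = z - X @ beta[1:]
        except np.linalg.LinAlgError:  # pragma: no cover
            log.warning("singular regression design for %s; rejection posterior used", name)
            z_adj = z
        q = np.percentile(z_adj, [2.5, 50.0, 97.5])
        back = lo + (hi - lo) * expit(q)
        rows[name] = {"q2.5": back[0], "median": back[1], "q97.5": back[2]}
        adj_cols[name] = lo + (hi - lo) * expit(z_adj)
    return PosteriorSummary(
        scenario=scenario,
        table=pd.DataFrame.from_dict(rows, orient="index"),
        n_retained=len(keep),
        adjusted=pd.DataFrame(adj_cols),
    )


# ---------------------------------------------------------------------------
# Model checking
# ---------------------------------------------------------------------------

def model_check(
    ref: ReferenceTable,
    observed: pd.Series,
    n_components: int = 5,
    band: tuple[float, float] = (2.5, 97.5),
) -> dict:
    """PCA projection of the observed statistics against the simulated cloud.

    Returns per-component observed coordinates, percentile bands over the
    simulated rows, and whether the observed point lies inside every band.
    """
    if ref.n_rows < 100:
        raise ValueError("model check needs at least 100 simulated rows")
    norm_stats, mad, cols = ref.normalized()
    obs = (observed[cols] / mad).to_numpy()
    X = norm_stats.to_numpy()
    k = min(n_components, X.shape[1], X.shape[0])
    pca = PCA(n_components=k)
    Z = pca.fit_transform(X)
    zo = pca.transform(obs.reshape(1, -1))[0]
    lo = np.percentile(Z, band[0], axis=0)
    hi = np.percentile(Z, band[1], axis=0)
    inside = (zo >= lo) & (zo <= hi)
    return {
        "components": k,
        "observed": zo,
        "band_low": lo,
        "band_high": hi,
        "inside": inside,
        "all_inside": bool(inside.all()),
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "component_variances": Z.var(axis=0),
    }


# ---------------------------------------------------------------------------
# Reporting arithmetic
# ---------------------------------------------------------------------------

def percent_size_change(n_post: float, n_pre: float) -> int:
    """Signed percent change 100*(n_post - n_pre)/n_pre, rounded to an integer."""
    if n_pre <= 0:
        raise ValueError("pre-change size must be positive")
    return int(round(100.0 * (n_post - n_pre) / n_pre))


def generations_to_years(
    g: float,
    generation_time: float = 4.0,
    present_year: int = 2010,
) -> tuple[float, float]:
    """(years before present, calendar year) for a time in generations."""
    if g < 0 or generation_time < 0:
        raise ValueError("generations and generation time must be non-negative")
    years = g * generation_time
    return years, present_year - years
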
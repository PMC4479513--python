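"""Diploid microsatellite genotype tables and GENEPOP text I/O.

The central container is :class:`GenotypeTable`: an individuals x loci x 2
integer array of allele states in *repeat units*, with a population label per
individual.  Missing genotypes are whole-pair missing and coded 0.

GENEPOP dialect notes
---------------------
* Both 2- and 3-digit allele codings are accepted; "00"/"000" alleles mark a
  missing genotype (a half-missing pair is treated as fully missing).
* Plain GENEPOP carries no population names, so the writer emits individual
  identifiers as ``<population>:<individual>`` and the reader recovers the
  label from the prefix before the first ``:``.  Files without that prefix get
  labels ``pop1``, ``pop2``, ...
* When a ``repeat_units`` mapping (locus -> motif length in bp) is supplied,
  raw fragment-size codes are floor-divided by the motif length at ingest so
  that downstream statistics (M-ratio, mutation models) operate on a
  repeat-unit lattice.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "GenotypeTable",
    "PopulationGroup",
    "GenepopParseError",
    "read_genepop",
    "write_genepop",
    "read_metadata",
    "write_metadata",
]

#: Sentinel allele state for a missing genotype.
MISSING = 0


class GenepopParseError(ValueError):
    """Raised for malformed GENEPOP input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass
class GenotypeTable:
    """Diploid allele-size matrix with population labels.

    Parameters
    ----------
    individuals
        Ordered individual identifiers (unique).
    loci
        Ordered locus names (unique).
    alleles
        Integer array of shape ``(n_individuals, n_loci, 2)``; allele states
        are positive integers in repeat units, ``0`` marks a missing pair.
    populations
        Population label per individual, parallel to ``individuals``.
    repeat_unit_of
        Optional mapping locus -> motif length (bp) recorded at ingest.
    """

    individuals: list[str]
    loci: list[str]
    alleles: np.ndarray
    populations: list[str]
    repeat_unit_of: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        n_ind, n_loc = len(self.individuals), len(self.loci)
        if self.alleles.shape != (n_ind, n_loc, 2):
            raise ValueError(
                f"allele array shape {self.alleles.shape} does not match "
                f"{n_ind} individuals x {n_loc} loci x 2"
            )
        if len(self.populations) != n_ind:
            raise ValueError("populations list must parallel individuals")
        if len(set(self.individuals)) != n_ind:
            raise ValueError("individual identifiers must be unique")
        if len(set(self.loci)) != n_loc:
            raise ValueError("locus names must be unique")
        if np.any(self.alleles < 0):
            raise ValueError("allele states must be non-negative integers")
        # whole-pair missing: forbid half-missing genotypes
        one_missing = (self.alleles == MISSING).sum(axis=2) == 1
        if np.any(one_missing):
            i, j = np.argwhere(one_missing)[0]
            raise ValueError(
                f"half-missing genotype for individual {self.individuals[i]!r} "
                f"at locus {self.loci[j]!r}"
            )

    # -- basic accessors -----------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def population_labels(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    @property
    def population_of(self) -> dict[str, str]:
        return dict(zip(self.individuals, self.populations))

    def population_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for p in self.populations:
            sizes[p] = sizes.get(p, 0) + 1
        return sizes

    def pop_indices(self, population: str) -> np.ndarray:
        idx = np.array([i for i, p in enumerate(self.populations) if p == population])
        if idx.size == 0:
            raise KeyError(f"population {population!r} not in table")
        return idx

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"locus {locus!r} not in table") from None

    def genotypes(self, population: str, locus_idx: int) -> np.ndarray:
        """Non-missing (m, 2) genotype array for one population at one locus."""
        sub = self.alleles[self.pop_indices(population), locus_idx, :]
        return sub[sub[:, 0] != MISSING]

    def allele_counts(self, population: str, locus_idx: int) -> tuple[np.ndarray, np.ndarray]:
        """(states, counts) of gene copies in one population at one locus."""
        g = self.genotypes(population, locus_idx).ravel()
        return np.unique(g, return_counts=True)

    def subset_populations(self, populations: Sequence[str]) -> "GenotypeTable":
        keep = set(populations)
        idx = [i for i, p in enumerate(self.populations) if p in keep]
        missing = keep - set(self.populations)
        if missing:
            raise KeyError(f"populations not in table: {sorted(missing)}")
        return GenotypeTable(
            individuals=[self.individuals[i] for i in idx],
            loci=list(self.loci),
            alleles=self.alleles[idx].copy(),
            populations=[self.populations[i] for i in idx],
            repeat_unit_of=dict(self.repeat_unit_of) if self.repeat_unit_of else None,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.loci == other.loci
            and self.populations == other.populations
            and np.array_equal(self.alleles, other.alleles)
        )


@dataclass(frozen=True)
class PopulationGroup:
    """A named, disjoint group of populations (e.g. clean vs metal-impacted)."""

    name: str
    members: tuple[str, ...]

    def __init__(self, name: str, members: Iterable[str]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "members", tuple(members))
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"group {name!r} has duplicate members")

    def validate_against(self, table: GenotypeTable) -> None:
        missing = set(self.members) - set(table.population_labels)
        if missing:
            raise KeyError(f"group {self.name!r} members not in table: {sorted(missing)}")


# ---------------------------------------------------------------------------
# GENEPOP reading / writing
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def read_genepop(
    path: str | Path,
    repeat_units: Mapping[str, int] | None = None,
) -> GenotypeTable:
    """Read a GENEPOP file into a :class:`GenotypeTable`.

    ``repeat_units`` maps locus name -> motif length; when given, allele codes
    for that locus are floor-divided by the motif length to yield repeat
    units.  Codes of 0 are missing.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenepopParseError("empty file")

    # header: title line then locus names (one per line, or comma-separated)
    loci: list[str] = []
    body_start = None
    for ln, raw in enumerate(lines[1:], start=2):
        if _POP_RE.match(raw):
            body_start = ln
            break
        for name in raw.split(","):
            name = name.strip()
            if name:
                loci.append(name)
    if body_start is None:
        raise GenepopParseError("no 'Pop' delimiter found", line=len(lines))
    if not loci:
        raise GenepopParseError("no locus names in header", line=2)

    individuals: list[str] = []
    populations: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_counter = 0
    current_pop: str | None = None
    digit_width: int | None = None

    def _fresh_pop() -> None:
        nonlocal pop_counter, current_pop
        pop_counter += 1
        current_pop = None  # decided from first individual id

    _fresh_pop()
    for ln, raw in enumerate(lines[body_start:], start=body_start + 1):
        if not raw.strip():
            continue
        if _POP_RE.match(raw):
            _fresh_pop()
            continue
        if "," not in raw:
            raise GenepopParseError("genotype line missing ',' separator", line=ln)
        ident, geno_part = raw.split(",", 1)
        ident = ident.strip()
        codes = geno_part.split()
        if len(codes) != len(loci):
            raise GenepopParseError(
                f"expected {len(loci)} genotypes, found {len(codes)}", line=ln
            )
        if current_pop is None:
            if ":" in ident:
                current_pop = ident.split(":", 1)[0]
            else:
                current_pop = f"pop{pop_counter}"
        if ":" in ident:
            pop_label, ind_id = ident.split(":", 1)
            if pop_label != current_pop:
                raise GenepopParseError(
                    f"population prefix {pop_label!r} differs from {current_pop!r} "
                    "within one Pop block",
                    line=ln,
                )
        else:
            ind_id = ident

        pair_row: list[tuple[int, int]] = []
        for li, code in enumerate(codes):
            if not code.isdigit():
                raise GenepopParseError(f"non-numeric genotype {code!r}", line=ln)
            if len(code) not in (4, 6):
                raise GenepopParseError(
                    f"genotype {code!r} has width {len(code)}; expected 4 or 6 digits",
                    line=ln,
                )
            w = len(code) // 2
            if digit_width is None:
                digit_width = w
            elif w != digit_width:
                raise GenepopParseError(
                    f"mixed {2 * digit_width}- and {len(code)}-digit codings", line=ln
                )
            a, b = int(code[:w]), int(code[w:])
            if a == 0 or b == 0:
                a = b = MISSING
            elif repeat_units is not None and loci[li] in repeat_units:
                motif = repeat_units[loci[li]]
                a, b = a // motif, b // motif
                if a <= 0 or b <= 0:
                    raise GenepopParseError(
                        f"allele code smaller than motif length at locus {loci[li]!r}",
                        line=ln,
                    )
            pair_row.append((a, b))
        individuals.append(ind_id)
        populations.append(current_pop)
        rows.append(pair_row)

    if not rows:
        raise GenepopParseError("no genotype rows", line=len(lines))
    alleles = np.array(rows, dtype=np.int64)
    ru = dict(repeat_units) if repeat_units is not None else None
    return GenotypeTable(individuals, loci, alleles, populations, repeat_unit_of=ru)


def write_genepop(
    table: GenotypeTable,
    path: str | Path,
    title: str = "msatpop genotype export",
    digit_width: int = 3,
) -> Path:
    """Write a table as GENEPOP text; round-trips through :func:`read_genepop`."""
    if table.n_loci == 0:
        raise ValueError("cannot write a table with no loci")
    if digit_width not in (2, 3):
        raise ValueError("digit_width must be 2 or 3")
    limit = 10**digit_width - 1
    if int(table.alleles.max(initial=0)) > limit:
        raise ValueError(
            f"allele state {int(table.alleles.max())} exceeds the "
            f"{digit_width}-digit GENEPOP coding (max {limit})"
        )
    out = [title]
    out.extend(table.loci)
    for pop in table.population_labels:
        out.append("Pop")
        for i in table.pop_indices(pop):
            codes = [
                f"{a:0{digit_width}d}{b:0{digit_width}d}"
                for a, b in table.alleles[i]
            ]
            out.append(f"{pop}:{table.individuals[i]} ,  " + " ".join(codes))
    p = Path(path)
    p.write_text("\n".join(out) + "\n")
    return p


# ---------------------------------------------------------------------------
# Sidecar metadata (population -> group, locus -> motif length)
# ---------------------------------------------------------------------------

def write_metadata(
    path: str | Path,
    pop_to_group: Mapping[str, str],
    locus_motif: Mapping[str, int],
) -> Path:
    """Write the tab-separated sidecar mapping used next to GENEPOP files."""
    rows = ["#kind\tname\tvalue"]
    rows += [f"population\t{p}\t{g}" for p, g in pop_to_group.items()]
    rows += [f"locus\t{l}\t{m}" for l, m in locus_motif.items()]
    p = Path(path)
    p.write_text("\n".join(rows) + "\n")
    return p


def read_metadata(path: str | Path) -> tuple[dict[str, str], dict[str, int]]:
    pop_to_group: dict[str, str] = {}
    locus_motif: dict[str, int] = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        parts = raw.split("\t")
        if len(parts) != 3:
            raise ValueError(f"metadata line {ln}: expected 3 tab-separated fields")
        kind, name, value = parts
        if kind == "population":
            pop_to_group[name] = value
        elif kind == "locus":
            locus_motif[name] = int(value)
        else:
            raise ValueError(f"metadata line {ln}: unknown kind {kind!r}")
    return pop_to_group, locus_motif


def groups_from_metadata(pop_to_group: Mapping[str, str]) -> list[PopulationGroup]:
    """Build :class:`PopulationGroup` objects from a population->group mapping."""
    by_group: dict[str, list[str]] = {}
    for pop, grp in pop_to_group.items():
        by_group.setdefault(grp, []).append(pop)
    return [PopulationGroup(g, members) for g, members in by_group.items()]
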
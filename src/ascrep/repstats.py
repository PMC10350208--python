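"""Clonality, expansion, overlap, and connectivity statistics.

All statistics operate on a :class:`~ascrep.lineage.LineageTable` and mirror
the standard repertoire readouts for sorted cell populations of one subject:

* rank-abundance ("clonality") profiles — lineages size-ranked in descending
  order, with per-lineage repertoire fractions and their cumulative sum;
* an expanded-clone rule on the rank profile — a clone is in the expanded set
  when it sits at or above the deepest consecutive rank-to-rank drop of at
  least 0.1 percentage points of repertoire share;
* the Morisita-Horn overlap index between two populations' lineage fraction
  vectors, 0 for disjoint lineage sets and 1 for identical relative
  abundances (the classical integer-count Morisita index is available as an
  option);
* clonal connectivity — the percentage of a reference population's lineages
  (all, expanded-only, or top-N by size) that are also detected in another
  population — and sharing curves over a grid of top-N cutoffs;
* a link table of lineages shared between population pairs, suitable for
  chord/Circos rendering.

Clone presence and default clone size use unique retained-sequence counts,
not duplicate-weighted counts, so presence/absence does not depend on read
depth weighting.  Fraction arithmetic that feeds threshold decisions is done
in exact rationals; reported percentages are rounded only at output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .lineage import LineageTable

__all__ = [
    "RankedCloneProfile",
    "ExpandedSet",
    "rank_profile",
    "top_clone_composition",
    "detect_expanded",
    "morisita_horn",
    "morisita",
    "overlap_matrix",
    "connectivity",
    "sharing_curve",
    "link_table",
]

DEFAULT_EXPANDED_PP = 0.1
DEFAULT_TOPN_GRID = (5, 10, 25, 50, 100)


@dataclass
class RankedCloneProfile:
    """Size-ranked clone profile of one population.

    ``sizes`` are integer clone sizes sorted non-increasing (ties broken by
    lineage_id for determinism); ``fractions`` are size/total and sum to 1;
    ``cumulative`` reaches 1 at the last rank.
    """

    population: str
    lineage_ids: list[int]
    sizes: list[int]
    total: int

    @property
    def fractions(self) -> np.ndarray:
        return np.asarray(self.sizes, dtype=float) / self.total

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.fractions)

    def fraction_exact(self, rank: int) -> Fraction:
        """Repertoire share of the clone at 1-based ``rank``, exact."""
        return Fraction(self.sizes[rank - 1], self.total)

    def __len__(self) -> int:
        return len(self.sizes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.sizes) + 1),
                "lineage_id": self.lineage_ids,
                "population": self.population,
                "size": self.sizes,
                "fraction": self.fractions,
                "cumulative": self.cumulative,
            }
        )


@dataclass
class ExpandedSet:
    """Expanded clones of one population: a prefix of the rank order."""

    population: str
    threshold_pp: float
    lineage_ids: list[int]
    boundary_rank: int  # 0 when the set is empty

    def __len__(self) -> int:
        return len(self.lineage_ids)


def rank_profile(
    table: LineageTable, population: str, weighted: bool = False
) -> RankedCloneProfile:
    """Size-rank the lineages of one population in descending order."""
    if population not in table.populations:
        raise ValueError(f"unknown population {population!r}")
    vec = table.size_vector(population, weighted=weighted)
    if not vec:
        raise ValueError(f"population {population!r} has no sequences")
    order = sorted(vec, key=lambda l: (-vec[l], l))
    sizes = [vec[l] for l in order]
    return RankedCloneProfile(
        population=population,
        lineage_ids=order,
        sizes=sizes,
        total=sum(sizes),
    )


def top_clone_composition(
    profile: RankedCloneProfile,
    reference: RankedCloneProfile,
    n_top: int = 10,
) -> pd.DataFrame:
    """Fractions, in ``profile``, of the reference population's top clones.

    For each of the reference's ``n_top`` largest lineages, reports its rank
    and fraction in the reference and its fraction in ``profile`` (0 when
    absent), plus a final ``remainder`` row carrying the rest of ``profile``'s
    mass — the numbers behind a stacked-bar composition display.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    top = reference.lineage_ids[:n_top]
    own = dict(zip(profile.lineage_ids, profile.fractions))
    rows = []
    for rank, lid in enumerate(top, start=1):
        rows.append(
            {
                "reference_rank": rank,
                "lineage_id": lid,
                "reference_fraction": reference.fractions[rank - 1],
                "fraction": own.get(lid, 0.0),
            }
        )
    remainder = 1.0 - sum(r["fraction"] for r in rows)
    rows.append(
        {
            "reference_rank": 0,
            "lineage_id": -1,
            "reference_fraction": 1.0 - float(np.sum(reference.fractions[:n_top])),
            "fraction": remainder,
        }
    )
    out = pd.DataFrame(rows)
    out["population"] = profile.population
    out["reference_population"] = reference.population
    return out


def detect_expanded(
    profile: RankedCloneProfile,
    threshold_pp: float | str = DEFAULT_EXPANDED_PP,
    rule: str = "deepest",
) -> ExpandedSet:
    """Delimit the abnormally expanded head of a rank profile.

    With clone shares f_1 >= f_2 >= ... expressed in percent, a consecutive
    pair (i, i+1) *qualifies* when f_i - f_{i+1} >= ``threshold_pp``
    percentage points.  Only observed consecutive pairs are scanned (no
    phantom f_{n+1} = 0).

    rule="deepest" (default): the boundary r* is the LARGEST qualifying i and
    the expanded set is ranks 1..r* — everything above the deepest qualifying
    drop, matching the visual elbow of rank plots.  rule="prefix": the
    maximal prefix of qualifying drops (r* = largest i such that pairs
    1..i all qualify).  Empty set when no pair qualifies.

    Comparisons are exact: shares are rationals size/total and the threshold
    is parsed from its decimal representation, so a drop of exactly the
    threshold qualifies.
    """
    if rule not in ("deepest", "prefix"):
        raise ValueError(f"unknown expanded-set rule {rule!r}")
    thr = Fraction(str(threshold_pp))
    n = len(profile)
    boundary = 0
    for i in range(1, n):  # pair (i, i+1), 1-based
        drop_pp = Fraction((profile.sizes[i - 1] - profile.sizes[i]) * 100, profile.total)
        if drop_pp >= thr:
            boundary = i
        elif rule == "prefix":
            break
    return ExpandedSet(
        population=profile.population,
        threshold_pp=float(thr),
        lineage_ids=profile.lineage_ids[:boundary],
        boundary_rank=boundary,
    )


def _count_vectors(table: LineageTable, pop_a: str, pop_b: str, weighted: bool):
    a = table.size_vector(pop_a, weighted=weighted)
    b = table.size_vector(pop_b, weighted=weighted)
    if not a:
        raise ValueError(f"population {pop_a!r} has no sequences")
    if not b:
        raise ValueError(f"population {pop_b!r} has no sequences")
    union = sorted(set(a) | set(b))
    x = [a.get(l, 0) for l in union]
    y = [b.get(l, 0) for l in union]
    return x, y


def morisita_horn(
    table: LineageTable, pop_a: str, pop_b: str, weighted: bool = False
) -> float:
    """Morisita-Horn overlap of two populations' lineage fraction vectors.

    MH = 2 sum(p_i q_i) / (sum(p_i^2) + sum(q_i^2)) with p, q the lineage
    fractions over the union of lineage sets.  Computed in exact integer
    arithmetic on clone counts, so identical fraction vectors give exactly
    1.0 and disjoint lineage sets exactly 0.0.
    """
    x, y = _count_vectors(table, pop_a, pop_b, weighted)
    sx, sy = sum(x), sum(y)
    cross = sum(xi * yi for xi, yi in zip(x, y))
    if cross == 0:
        return 0.0
    denom = sy * sy * sum(xi * xi for xi in x) + sx * sx * sum(yi * yi for yi in y)
    return float(Fraction(2 * sx * sy * cross, denom))


def morisita(
    table: LineageTable, pop_a: str, pop_b: str, weighted: bool = False
) -> float:
    """Classical Morisita overlap index on integer clone counts.

    C = 2 sum(x_i y_i) / ((l_x + l_y) X Y) with l_x = sum x(x-1)/(X(X-1)).
    Requires at least 2 sequences in each population.
    """
    x, y = _count_vectors(table, pop_a, pop_b, weighted)
    sx, sy = sum(x), sum(y)
    if sx < 2 or sy < 2:
        raise ValueError("classical Morisita requires >= 2 sequences per population")
    cross = sum(xi * yi for xi, yi in zip(x, y))
    if cross == 0:
        return 0.0
    lx = Fraction(sum(xi * (xi - 1) for xi in x), sx * (sx - 1))
    ly = Fraction(sum(yi * (yi - 1) for yi in y), sy * (sy - 1))
    return float(Fraction(2 * cross) / ((lx + ly) * sx * sy))


def overlap_matrix(
    table: LineageTable,
    populations: Sequence[str] | None = None,
    variant: str = "morisita-horn",
    weighted: bool = False,
) -> pd.DataFrame:
    """Square symmetric matrix of pairwise overlap values, unit diagonal."""
    pops = list(populations) if populations is not None else table.populations
    fn = {"morisita-horn": morisita_horn, "morisita": morisita}[variant]
    mat = pd.DataFrame(1.0, index=pops, columns=pops)
    for a, b in combinations(pops, 2):
        val = fn(table, a, b, weighted=weighted)
        mat.loc[a, b] = val
        mat.loc[b, a] = val
    mat.index.name = "population"
    return mat


def _scoped_lineages(
    table: LineageTable,
    ref: str,
    scope: str,
    n: int | None,
    threshold_pp: float | str,
) -> tuple[list[int], bool]:
    """Reference lineages under a scope; flags top_n truncation."""
    profile = rank_profile(table, ref)
    truncated = False
    if scope == "all":
        scoped = profile.lineage_ids
    elif scope == "expanded":
        scoped = detect_expanded(profile, threshold_pp=threshold_pp).lineage_ids
    elif scope == "top_n":
        if n is None or n < 1:
            raise ValueError("scope='top_n' requires n >= 1")
        truncated = len(profile) < n
        scoped = profile.lineage_ids[:n]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return list(scoped), truncated


def connectivity(
    table: LineageTable,
    ref: str,
    other: str,
    scope: str = "all",
    n: int | None = None,
    threshold_pp: float | str = DEFAULT_EXPANDED_PP,
) -> float | None:
    """Percent of the reference population's scoped clones detected in ``other``.

    Scope is ``all`` lineages of ``ref``, its ``expanded`` set, or its
    ``top_n`` largest (with fewer than n available, all are used).  Presence
    in ``other`` means unique-sequence clone size > 0.  An empty scope (e.g.
    an empty expanded set) yields ``None`` — undefined, never coerced to 0.
    """
    if other not in table.populations:
        raise ValueError(f"unknown population {other!r}")
    scoped, _ = _scoped_lineages(table, ref, scope, n, threshold_pp)
    if not scoped:
        return None
    present = set(table.size_vector(other))
    shared = sum(1 for l in scoped if l in present)
    return 100.0 * shared / len(scoped)


def sharing_curve(
    table: LineageTable,
    ref: str,
    others: Iterable[str],
    n_grid: Sequence[int] = DEFAULT_TOPN_GRID,
) -> pd.DataFrame:
    """Percent of the reference's top-n clones shared with each other population.

    One row per (other population, n); ``n_available`` records how many
    clones were actually scoped when the reference holds fewer than n.
    """
    n_grid = list(n_grid)
    if any(n < 1 for n in n_grid) or sorted(n_grid) != n_grid:
        raise ValueError("n_grid must be ascending positive integers")
    profile = rank_profile(table, ref)
    rows = []
    for other in others:
        for n in n_grid:
            pct = connectivity(table, ref, other, scope="top_n", n=n)
            rows.append(
                {
                    "ref": ref,
                    "other": other,
                    "n": n,
                    "n_available": min(n, len(profile)),
                    "percent": pct,
                }
            )
    return pd.DataFrame(rows)


def link_table(table: LineageTable) -> pd.DataFrame:
    """One row per (lineage, ordered population pair) sharing that lineage.

    Columns: source_pop, target_pop, lineage_id, size_source, size_target —
    the inputs of a chord/Circos interconnectedness display.  Populations are
    ordered by their appearance in the table; each unordered pair appears
    once.
    """
    pops = table.populations
    if len(pops) < 2:
        raise ValueError("link_table requires >= 2 populations")
    vectors = {p: table.size_vector(p) for p in pops}
    rows = []
    for a, b in combinations(pops, 2):
        shared = sorted(set(vectors[a]) & set(vectors[b]))
        for lid in shared:
            rows.append(
                {
                    "source_pop": a,
                    "target_pop": b,
                    "lineage_id": lid,
                    "size_source": vectors[a][lid],
                    "size_target": vectors[b][lid],
                }
            )
    return pd.DataFrame(
        rows,
        columns=["source_pop", "target_pop", "lineage_id", "size_source", "size_target"],
    )
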
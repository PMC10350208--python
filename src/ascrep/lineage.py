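"""Clonal lineage assignment by V gene / J gene / CDR3 length / homology.

Rearrangements of one subject, pooled across all of its sorted populations,
are partitioned into clonal lineages: two sequences can belong to the same
lineage only if they share the same V gene, the same J gene, and the same
junction length; within such a group, lineages are the connected components
of the graph that links every pair of junctions with nucleotide identity at
or above the homology threshold (default 0.85, i.e. 85% CDR3 homology,
single linkage).

Identity is the exact rational ``matches / length`` and the threshold test is
performed in integer arithmetic (``matches >= ceil(threshold * length)``), so
a pair sitting exactly at the threshold is linked — 85% homology is read as
attained-at-85 — and no floating-point strictness artifacts can flip a
boundary pair.

Clustering across populations of one subject is joint: a lineage may span
populations, which is what the downstream connectivity statistics measure.
Clustering never pools across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .airr_io import Repertoire, normalize_gene_call, write_table

__all__ = [
    "DEFAULT_THRESHOLD",
    "LineageKey",
    "LineageTable",
    "junction_identity",
    "partition_by_key",
    "cluster_group",
    "assign_lineages",
]

DEFAULT_THRESHOLD = 0.85

# Columns of the per-sequence assignment frame of a LineageTable.
ASSIGNMENT_COLUMNS = (
    "sequence_id",
    "subject",
    "population",
    "lineage_id",
    "v_gene",
    "j_gene",
    "junction_length",
    "junction",
    "duplicate_count",
    "v_mutation_count",
)


@dataclass(frozen=True, order=True)
class LineageKey:
    """The exact-match part of the clonal-assignment rule."""

    v_gene: str
    j_gene: str
    junction_length: int


@dataclass
class LineageTable:
    """Global lineage assignments for one subject across its populations.

    ``assignments`` holds one row per retained rearrangement with its
    ``lineage_id`` (integers 1..K, canonical: ordered by the lexicographically
    smallest member sequence_id).  ``sizes`` holds per (lineage, population)
    sizes, both as unique retained-sequence counts (``n_seq``, the default
    clone size) and duplicate-weighted counts (``n_dup``).
    """

    subject: str
    assignments: pd.DataFrame = field(repr=False)
    sizes: pd.DataFrame = field(repr=False)
    threshold: float = DEFAULT_THRESHOLD

    @property
    def populations(self) -> list[str]:
        return list(self.assignments["population"].drop_duplicates())

    @property
    def n_lineages(self) -> int:
        return int(self.assignments["lineage_id"].nunique())

    def lineage_keys(self) -> pd.DataFrame:
        cols = ["lineage_id", "v_gene", "j_gene", "junction_length"]
        return self.assignments[cols].drop_duplicates().reset_index(drop=True)

    def population_total(self, population: str, weighted: bool = False) -> int:
        sub = self.assignments[self.assignments["population"] == population]
        if weighted:
            return int(sub["duplicate_count"].sum())
        return int(len(sub))

    def size_vector(self, population: str, weighted: bool = False) -> dict[int, int]:
        """Clone sizes of one population as lineage_id -> count (size > 0 only)."""
        col = "n_dup" if weighted else "n_seq"
        sub = self.sizes[self.sizes["population"] == population]
        return {int(l): int(c) for l, c in zip(sub["lineage_id"], sub[col]) if c > 0}

    def write(self, path) -> None:
        cols = ["sequence_id", "subject", "population", "lineage_id",
                "v_gene", "j_gene", "junction_length"]
        write_table(self.assignments[cols], path)


def _threshold_fraction(threshold: float | str | Fraction) -> Fraction:
    if isinstance(threshold, Fraction):
        frac = threshold
    else:
        frac = Fraction(str(threshold))
    if not 0 < frac <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    return frac


def min_matches_for(length: int, threshold: float | str | Fraction) -> int:
    """Smallest match count m with m/length >= threshold, exactly."""
    frac = _threshold_fraction(threshold)
    return -(-frac.numerator * length // frac.denominator)  # ceil


def junction_identity(a: str, b: str) -> float:
    """Fraction of positions at which two equal-length junctions agree.

    Symmetric; ``junction_identity(a, a) == 1.0``.  Callers partition by
    length first: unequal lengths are an error, not identity 0.
    """
    if len(a) != len(b) or len(a) == 0:
        raise ValueError(
            f"junction identity requires equal nonzero lengths, got {len(a)} and {len(b)}"
        )
    matches = sum(x == y for x, y in zip(a, b))
    return matches / len(a)


def partition_by_key(frame: pd.DataFrame) -> dict[LineageKey, np.ndarray]:
    """Group pooled rearrangements by (v_gene, j_gene, junction_length).

    ``frame`` must carry normalized ``v_gene``/``j_gene`` columns; returns a
    mapping from key to the integer row positions of its members.
    """
    groups: dict[LineageKey, np.ndarray] = {}
    if len(frame) == 0:
        return groups
    grouped = frame.groupby(["v_gene", "j_gene", "junction_length"], sort=True)
    for (v, j, length), idx in grouped.indices.items():
        groups[LineageKey(str(v), str(j), int(length))] = np.sort(idx)
    return groups


class _DisjointSet:
    __slots__ = ("parent",)

    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        parent = self.parent
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def cluster_group(
    junctions: Sequence[str],
    threshold: float | str | Fraction = DEFAULT_THRESHOLD,
    sequence_ids: Sequence[str] | None = None,
) -> list[int]:
    """Single-linkage clustering of equal-length junctions at a homology threshold.

    Builds the graph with an edge between any pair whose identity is >= the
    threshold (inclusive: identity exactly at the threshold links the pair)
    and returns, per input junction, the label of its connected component.
    Labels are 0..k-1, ordered by each component's smallest member
    ``sequence_id`` (input order used when ids are not given), so the output
    is deterministic and permutation-invariant up to that canonical order.
    """
    n = len(junctions)
    if n == 0:
        return []
    length = len(junctions[0])
    if any(len(j) != length for j in junctions):
        raise ValueError("cluster_group requires equal-length junctions")
    min_matches = min_matches_for(length, threshold)

    # Identical strings are trivially one clone; cluster unique junctions only.
    uniq: dict[str, int] = {}
    member_of = np.empty(n, dtype=np.int64)
    for i, j in enumerate(junctions):
        member_of[i] = uniq.setdefault(j, len(uniq))
    m = len(uniq)

    dsu = _DisjointSet(m)
    if m > 1 and min_matches <= length:
        arr = np.frombuffer("".join(uniq).encode("ascii"), dtype=np.uint8)
        arr = arr.reshape(m, length)
        for i in range(m - 1):
            matches = (arr[i + 1:] == arr[i]).sum(axis=1)
            for off in np.nonzero(matches >= min_matches)[0]:
                dsu.union(i, i + 1 + int(off))

    roots = np.array([dsu.find(member_of[i]) for i in range(n)])
    # Canonical labels: order components by their smallest member sequence_id.
    if sequence_ids is None:
        first = {}
        for i, r in enumerate(roots):
            first.setdefault(r, i)
        order = sorted(first, key=first.get)
    else:
        smallest: dict[int, str] = {}
        for i, r in enumerate(roots):
            sid = str(sequence_ids[i])
            if r not in smallest or sid < smallest[r]:
                smallest[r] = sid
        order = sorted(smallest, key=smallest.get)
    relabel = {r: k for k, r in enumerate(order)}
    return [relabel[r] for r in roots]


def assign_lineages(
    repertoires: Iterable[Repertoire],
    threshold: float | str | Fraction = DEFAULT_THRESHOLD,
) -> LineageTable:
    """Assign every rearrangement of one subject to a clonal lineage.

    Pools all populations of the subject, partitions by
    (v_gene, j_gene, junction_length), then single-linkage-clusters each
    group's junctions at the homology threshold.  Lineage ids are integers
    1..K, globally unique per subject and canonically ordered by each
    lineage's smallest member sequence_id, so they do not depend on input
    order.  Per-population clone sizes are tabulated both as unique sequence
    counts and as duplicate-weighted counts.
    """
    reps = list(repertoires)
    if not reps:
        raise ValueError("assign_lineages requires at least one repertoire")
    subjects = {r.subject for r in reps}
    if len(subjects) != 1:
        raise ValueError(f"assign_lineages pools one subject, got {sorted(subjects)}")
    subject = reps[0].subject

    pooled = pd.concat([r.frame for r in reps], ignore_index=True)
    if len(pooled) == 0:
        raise ValueError("assign_lineages: no rearrangements")
    pooled = pooled.copy()
    pooled["v_gene"] = pooled["v_call"].map(normalize_gene_call)
    pooled["j_gene"] = pooled["j_call"].map(normalize_gene_call)

    labels = np.empty(len(pooled), dtype=np.int64)
    lineage_minid: list[tuple[str, int]] = []  # (smallest sequence_id, provisional id)
    next_id = 0
    seq_ids = pooled["sequence_id"].to_numpy()
    junctions = pooled["junction"].to_numpy()
    for key, idx in partition_by_key(pooled).items():
        group_labels = cluster_group(
            [junctions[i] for i in idx],
            threshold=threshold,
            sequence_ids=[seq_ids[i] for i in idx],
        )
        k = max(group_labels) + 1
        mins = [None] * k
        for pos, lab in zip(idx, group_labels):
            labels[pos] = next_id + lab
            sid = str(seq_ids[pos])
            if mins[lab] is None or sid < mins[lab]:
                mins[lab] = sid
        for lab in range(k):
            lineage_minid.append((mins[lab], next_id + lab))
        next_id += k

    # Canonical global ids 1..K by smallest member sequence_id.
    lineage_minid.sort()
    remap = {prov: final + 1 for final, (_, prov) in enumerate(lineage_minid)}
    pooled["lineage_id"] = [remap[l] for l in labels]

    assignments = pooled[list(ASSIGNMENT_COLUMNS)].reset_index(drop=True)
    sizes = (
        assignments.groupby(["lineage_id", "population"], sort=True)
        .agg(n_seq=("sequence_id", "size"), n_dup=("duplicate_count", "sum"))
        .reset_index()
    )
    return LineageTable(
        subject=subject,
        assignments=assignments,
        sizes=sizes,
        threshold=float(_threshold_fraction(threshold)),
    )
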
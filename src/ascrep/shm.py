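"""Somatic hypermutation load and intraclonal divergence summaries.

V-region mutation counts are taken from the input column (annotated upstream
by the aligner), never recomputed from sequence.  Per-population summaries
use only sequences with non-missing counts.  Intraclonal divergence checks
whether multi-member lineages show sequence spread (mean pairwise junction
mismatches) or a sequential progression of somatic mutation, operationalized
as the within-lineage range of mutation counts against a configurable cutoff
(default 5 — a tool parameter, not a published constant).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .lineage import LineageTable

__all__ = ["shm_load", "intraclonal_divergence", "DEFAULT_DIVERGENCE_CUTOFF"]

DEFAULT_DIVERGENCE_CUTOFF = 5


def shm_load(table: LineageTable, populations=None) -> pd.DataFrame:
    """Location/spread statistics of v_mutation_count per population.

    Columns: population, n_sequences (with mutation data), mean, median,
    q25, q75, iqr.  Populations lacking any mutation data are reported with
    n_sequences=0 and missing statistics, never silently dropped.
    """
    pops = list(populations) if populations is not None else table.populations
    rows = []
    for pop in pops:
        sub = table.assignments.loc[
            table.assignments["population"] == pop, "v_mutation_count"
        ].dropna()
        if len(sub) == 0:
            rows.append(
                {"population": pop, "n_sequences": 0, "mean": np.nan,
                 "median": np.nan, "q25": np.nan, "q75": np.nan, "iqr": np.nan}
            )
            continue
        vals = sub.to_numpy(dtype=float)
        q25, q75 = np.percentile(vals, [25, 75])
        rows.append(
            {
                "population": pop,
                "n_sequences": int(len(vals)),
                "mean": float(vals.mean()),
                "median": float(np.median(vals)),
                "q25": float(q25),
                "q75": float(q75),
                "iqr": float(q75 - q25),
            }
        )
    return pd.DataFrame(rows)


def _mean_pairwise_mismatches(junctions: np.ndarray) -> float:
    """Mean Hamming distance over all unordered pairs of equal-length strings.

    Column-wise character counting gives the exact all-pairs mean in
    O(m * L) instead of O(m^2 * L).
    """
    m = len(junctions)
    arr = np.frombuffer("".join(junctions).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(m, len(junctions[0]))
    n_pairs = m * (m - 1) // 2
    same = 0
    for col in range(arr.shape[1]):
        counts = np.bincount(arr[:, col])
        same += int((counts * (counts - 1) // 2).sum())
    # mismatching pairs contribute per column: n_pairs - same_pairs(col)
    total_mismatches = n_pairs * arr.shape[1] - same
    return total_mismatches / n_pairs


def intraclonal_divergence(
    table: LineageTable, cutoff: int = DEFAULT_DIVERGENCE_CUTOFF
) -> pd.DataFrame:
    """Per multi-member lineage: junction spread and mutation-count range.

    Columns: lineage_id, n_members, mean_pairwise_junction_mismatches,
    mutation_range (max - min of v_mutation_count over members with data;
    missing when fewer than 2 members carry counts), per-population mean
    mutation counts (one ``mean_mut_<pop>`` column per population), and a
    ``divergent`` flag set when mutation_range exceeds ``cutoff``.

    Singleton lineages are excluded, never zero-filled: divergence is
    undefined for them.
    """
    frame = table.assignments
    pops = table.populations
    rows = []
    for lid, grp in frame.groupby("lineage_id", sort=True):
        if len(grp) < 2:
            continue
        mean_mm = _mean_pairwise_mismatches(grp["junction"].to_numpy())
        muts = grp["v_mutation_count"].dropna()
        if len(muts) >= 2:
            mut_range = float(muts.max() - muts.min())
            divergent = mut_range > cutoff
        else:
            mut_range = np.nan
            divergent = False
        row = {
            "lineage_id": int(lid),
            "n_members": int(len(grp)),
            "mean_pairwise_junction_mismatches": mean_mm,
            "mutation_range": mut_range,
            "divergent": divergent,
        }
        for pop in pops:
            pop_muts = grp.loc[grp["population"] == pop, "v_mutation_count"].dropna()
            row[f"mean_mut_{pop}"] = float(pop_muts.mean()) if len(pop_muts) else np.nan
        rows.append(row)
    cols = ["lineage_id", "n_members", "mean_pairwise_junction_mismatches",
            "mutation_range", "divergent"] + [f"mean_mut_{p}" for p in pops]
    return pd.DataFrame(rows, columns=cols)
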
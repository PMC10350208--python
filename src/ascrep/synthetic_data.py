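"""Synthetic multi-population AIRR repertoires with known clonal structure.

The generator emulates the repertoire structure of sorted antibody-secreting
cell populations from one subject:

* a configurable number of clonal lineages, each with a founder junction and
  an exact-match key (V gene, J gene, junction length drawn from multiples of
  3 between 30 and 66 nt);
* heavy-tailed per-population clone sizes (Zipf law, default exponent 1.5);
* a lineage-sharing model across populations — either a global probability
  ``s`` that a lineage is present in any given population, or a
  home-population sharing matrix;
* within-lineage junction variants confined to a mutation radius of
  ``floor(0.075 * L)`` positions from the founder, so any two variants of a
  lineage have identity >= 1 - 2*0.075 = 0.85 — at or above the clustering
  threshold — while founders of distinct lineages sharing a key are kept at
  pairwise identity < 0.70 by rejection sampling.  The dead zone between
  0.85 and 0.70 makes lineage recovery by the pipeline unambiguous, so the
  generator's truth labels are an exact oracle;
* V/J calls drawn from a built-in catalog *with* allele suffixes (one entry
  lists two comma-separated calls) to exercise gene-call normalization;
* per-sequence duplicate counts (1 + Poisson) and V-region mutation counts
  (Poisson per-lineage base plus optional rounded-Gaussian per-sequence
  jitter, floored at 0; jitter 0 is the zero-jitter mode in which no lineage
  shows any mutation-count spread).

Everything is deterministic given the seed: identical config + seed produce
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .airr_io import Repertoire, write_table
from .lineage import min_matches_for

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimResult",
    "generate",
    "truth_connectivity",
    "write_simulation",
    "adversarial_pair",
    "inject_corruption",
    "V_CATALOG",
    "J_CATALOG",
]

# Raw annotation strings as an upstream aligner would emit them: allele
# suffixes everywhere, one entry with two comma-separated calls.  Gene usage
# frequencies are uniform — realistic usage biology is out of scope.
V_CATALOG = (
    "IGHV1-2*02",
    "IGHV1-69*01",
    "IGHV3-23*04, IGHV3-23D*01",
    "IGHV3-7*01",
    "IGHV3-30*03",
    "IGHV4-34*01",
    "IGHV4-59*01",
    "IGHV5-51*01",
)
J_CATALOG = ("IGHJ3*02", "IGHJ4*02", "IGHJ5*02", "IGHJ6*03")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_FOUNDER_MAX_IDENTITY = 0.70  # same-key founders must sit strictly below this


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated subject.

    Defaults mirror the sequencing design being emulated: four sorted
    populations labeled pop2..pop5 and a depth of about 50,000 sequences per
    population (scale ``sequences_per_population`` down for quick runs).
    """

    n_populations: int = 4
    n_lineages: int = 500
    sharing: float | Sequence[Sequence[float]] = 0.4
    sequences_per_population: int = 50_000
    zipf_alpha: float = 1.5
    junction_lengths: tuple[int, ...] = tuple(range(30, 67, 3))
    mutation_radius_fraction: float = 0.075
    shm_lambda: float = 8.0
    shm_jitter: float = 0.0
    duplicate_lambda: float = 0.3
    seed: int = 0
    subject: str = "S1"

    @property
    def populations(self) -> tuple[str, ...]:
        return tuple(f"pop{i + 2}" for i in range(self.n_populations))


@dataclass
class SimTruth:
    """Ground-truth lineage structure of a generated subject.

    ``sequences``: per emitted sequence its true lineage_id and population.
    ``lineages``: per lineage its key, founder junction, and base mutation
    count.  ``sizes``: realized per (lineage, population) clone sizes.  Every
    configured member lineage holds at least one sequence in each of its
    member populations, so configured and realized membership coincide.
    """

    subject: str
    sequences: pd.DataFrame = field(repr=False)
    lineages: pd.DataFrame = field(repr=False)
    sizes: pd.DataFrame = field(repr=False)

    def members(self, population: str) -> set[int]:
        sub = self.sizes[self.sizes["population"] == population]
        return set(int(l) for l in sub["lineage_id"])

    def labels(self) -> dict[str, int]:
        return dict(zip(self.sequences["sequence_id"], self.sequences["lineage_id"]))

    def sharing_fraction(self, ref: str, other: str) -> float:
        ref_set = self.members(ref)
        return len(ref_set & self.members(other)) / len(ref_set)


@dataclass
class SimResult:
    config: SimConfig
    repertoires: list[Repertoire]
    truth: SimTruth


class FeasibilityError(ValueError):
    """The configuration cannot be realized (e.g. founders cannot be separated)."""


def _draw_founders(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Lineage keys and founder junctions, same-key founders < 70% identity."""
    v_idx = rng.integers(0, len(V_CATALOG), size=config.n_lineages)
    j_idx = rng.integers(0, len(J_CATALOG), size=config.n_lineages)
    len_idx = rng.integers(0, len(config.junction_lengths), size=config.n_lineages)
    by_key: dict[tuple[int, int, int], list[np.ndarray]] = {}
    founders = []
    for li in range(config.n_lineages):
        key = (int(v_idx[li]), int(j_idx[li]), int(len_idx[li]))
        length = config.junction_lengths[key[2]]
        max_matches = min_matches_for(length, _FOUNDER_MAX_IDENTITY) - 1
        peers = by_key.setdefault(key, [])
        for _ in range(1000):
            cand = _BASES[rng.integers(0, 4, size=length)]
            if all(int((cand == p).sum()) <= max_matches for p in peers):
                break
        else:
            raise FeasibilityError(
                f"cannot separate {len(peers) + 1} same-key founders at "
                f"junction length {length}; use a longer junction support "
                "or fewer lineages"
            )
        peers.append(cand)
        founders.append(
            {
                "lineage_id": li + 1,
                "v_call": V_CATALOG[key[0]],
                "j_call": J_CATALOG[key[1]],
                "junction_length": length,
                "founder_junction": cand.tobytes().decode("ascii"),
            }
        )
    return pd.DataFrame(founders)


def _draw_memberships(config: SimConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """Per lineage, the boolean membership vector over populations.

    Global sharing probability s: i.i.d. Bernoulli(s) per population with
    rejection of all-absent draws (conditional on membership in any one
    population, the other memberships stay Bernoulli(s) — the property the
    connectivity statistics recover).  s == 0 degenerates to one uniform home
    population per lineage.  A matrix spec instead assigns a uniform home
    population and shares into population j with probability M[home][j].
    """
    k = config.n_populations
    out = []
    if isinstance(config.sharing, (int, float)):
        s = float(config.sharing)
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"sharing probability must be in [0, 1], got {s}")
        for _ in range(config.n_lineages):
            if s == 0.0:
                vec = np.zeros(k, dtype=bool)
                vec[rng.integers(0, k)] = True
            else:
                while True:
                    vec = rng.random(k) < s
                    if vec.any():
                        break
            out.append(vec)
    else:
        mat = np.asarray(config.sharing, dtype=float)
        if mat.shape != (k, k):
            raise ValueError(f"sharing matrix must be {k}x{k}, got {mat.shape}")
        for _ in range(config.n_lineages):
            home = int(rng.integers(0, k))
            vec = rng.random(k) < mat[home]
            vec[home] = True
            out.append(vec)
    return out


def _mutate(founder: np.ndarray, n_mut: int, rng: np.random.Generator) -> np.ndarray:
    """Copy of the founder with ``n_mut`` distinct positions changed."""
    var = founder.copy()
    if n_mut == 0:
        return var
    pos = rng.choice(len(founder), size=n_mut, replace=False)
    for p in pos:
        choices = _BASES[_BASES != var[p]]
        var[p] = choices[rng.integers(0, 3)]
    return var


def generate(config: SimConfig) -> SimResult:
    """Generate one subject's repertoires plus ground truth.

    Per population, its member lineages get one guaranteed sequence each and
    the remaining depth is distributed multinomially over Zipf weights
    ``rank**-alpha`` (ranks assigned by a per-population shuffle of the
    member lineages).  Raises :class:`FeasibilityError` when the depth cannot
    seat every member lineage or founders cannot be separated.
    """
    rng = np.random.default_rng(config.seed)
    lineages = _draw_founders(config, rng)
    memberships = _draw_memberships(config, rng)
    base_shm = rng.poisson(config.shm_lambda, size=config.n_lineages)
    lineages["base_mutation_count"] = base_shm

    pops = config.populations
    founder_arrays = [
        np.frombuffer(s.encode("ascii"), dtype=np.uint8)
        for s in lineages["founder_junction"]
    ]
    radii = [
        int(config.mutation_radius_fraction * L) for L in lineages["junction_length"]
    ]

    repertoires: list[Repertoire] = []
    truth_rows = []
    size_rows = []
    for pi, pop in enumerate(pops):
        member_ids = [li for li in range(config.n_lineages) if memberships[li][pi]]
        n_mem = len(member_ids)
        if n_mem == 0:
            raise FeasibilityError(f"population {pop} has no member lineages")
        n_seq = config.sequences_per_population
        if n_seq < n_mem:
            raise FeasibilityError(
                f"population {pop}: depth {n_seq} cannot seat {n_mem} lineages"
            )
        ranks = rng.permutation(n_mem) + 1
        weights = ranks.astype(float) ** -config.zipf_alpha
        counts = np.ones(n_mem, dtype=np.int64)
        counts += rng.multinomial(n_seq - n_mem, weights / weights.sum())

        recs = []
        for mi, li in enumerate(member_ids):
            founder = founder_arrays[li]
            radius = radii[li]
            row = lineages.iloc[li]
            for _ in range(int(counts[mi])):
                n_mut = int(rng.integers(0, radius + 1))
                junction = _mutate(founder, n_mut, rng).tobytes().decode("ascii")
                shm = int(base_shm[li])
                if config.shm_jitter > 0:
                    shm += int(round(rng.normal(0.0, config.shm_jitter)))
                recs.append(
                    (
                        row["v_call"],
                        row["j_call"],
                        junction,
                        int(row["junction_length"]),
                        1 + int(rng.poisson(config.duplicate_lambda)),
                        max(shm, 0),
                        int(row["lineage_id"]),
                    )
                )
            size_rows.append(
                {
                    "lineage_id": int(row["lineage_id"]),
                    "population": pop,
                    "size": int(counts[mi]),
                }
            )
        order = rng.permutation(len(recs))
        frame = pd.DataFrame(
            [recs[i] for i in order],
            columns=["v_call", "j_call", "junction", "junction_length",
                     "duplicate_count", "v_mutation_count", "lineage_id"],
        )
        frame.insert(
            0,
            "sequence_id",
            [f"{config.subject}_{pop}_seq{i:06d}" for i in range(len(frame))],
        )
        truth_rows.append(
            pd.DataFrame(
                {
                    "sequence_id": frame["sequence_id"],
                    "population": pop,
                    "lineage_id": frame["lineage_id"],
                }
            )
        )
        rep_frame = frame.drop(columns=["lineage_id"]).copy()
        rep_frame["population"] = pop
        rep_frame["subject"] = config.subject
        repertoires.append(Repertoire(config.subject, pop, rep_frame))

    truth = SimTruth(
        subject=config.subject,
        sequences=pd.concat(truth_rows, ignore_index=True),
        lineages=lineages,
        sizes=pd.DataFrame(size_rows),
    )
    return SimResult(config=config, repertoires=repertoires, truth=truth)


def truth_connectivity(truth: SimTruth, ref: str, other: str) -> float:
    """Ground-truth percent of ref's lineages also present in ``other``."""
    ref_set = truth.members(ref)
    if not ref_set:
        raise ValueError(f"population {ref!r} absent from truth")
    return 100.0 * len(ref_set & truth.members(other)) / len(ref_set)


def write_simulation(result: SimResult, out_dir) -> dict[str, Path]:
    """Write one AIRR TSV per population plus truth tables; return the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    airr_cols = ["sequence_id", "v_call", "j_call", "junction", "junction_length",
                 "duplicate_count", "v_mutation_count", "population", "subject"]
    for rep in result.repertoires:
        p = out_dir / f"{rep.population}.tsv"
        write_table(rep.frame[airr_cols], p)
        paths[rep.population] = p
    truth_path = out_dir / "truth.tsv"
    write_table(result.truth.sequences, truth_path)
    paths["truth"] = truth_path
    lineage_path = out_dir / "truth_lineages.tsv"
    write_table(result.truth.lineages, lineage_path)
    paths["truth_lineages"] = lineage_path
    return paths


def adversarial_pair(
    length: int, identity: float, rng: np.random.Generator | None = None
) -> tuple[str, str]:
    """Two junctions whose identity is exactly ``identity`` (boundary probe).

    ``identity * length`` must be an integer number of matches; used to place
    pairs exactly at (or one mismatch either side of) the clustering
    threshold.
    """
    rng = rng or np.random.default_rng(0)
    matches = identity * length
    if abs(matches - round(matches)) > 1e-9:
        raise ValueError(f"identity {identity} not realizable at length {length}")
    n_mismatch = length - int(round(matches))
    a = _BASES[rng.integers(0, 4, size=length)]
    b = _mutate(a, n_mismatch, rng)
    return a.tobytes().decode("ascii"), b.tobytes().decode("ascii")


def inject_corruption(
    frame: pd.DataFrame, fraction: float, seed: int = 0
) -> pd.DataFrame:
    """Corrupt a fraction of rearrangement rows to exercise validation.

    Alternates between injecting an ``N`` into the junction and emptying it.
    Returns a copy; row order unchanged.
    """
    rng = np.random.default_rng(seed)
    out = frame.copy()
    n_bad = int(round(fraction * len(out)))
    idx = rng.choice(len(out), size=n_bad, replace=False)
    for k, i in enumerate(np.sort(idx)):
        junction = out.iat[i, out.columns.get_loc("junction")]
        if k % 2 == 0 and junction:
            pos = int(rng.integers(0, len(junction)))
            out.iat[i, out.columns.get_loc("junction")] = (
                junction[:pos] + "N" + junction[pos + 1:]
            )
        else:
            out.iat[i, out.columns.get_loc("junction")] = ""
    return out
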
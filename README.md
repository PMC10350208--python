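# ascrep

Clonal repertoire analysis of sorted antibody-secreting cell (ASC)
populations from AIRR-seq rearrangement tables.

Circulating ASCs can be sorted by CD19/CD138 into populations spanning a
maturation gradient (pop2: CD19+CD138−, pop3: CD19+CD138+, pop4:
CD19−CD138−, pop5: CD19−CD138+). Whether these populations descend from
common B-cell precursors is readable from their B-cell receptor
repertoires: clonal lineages shared between populations imply shared
precursors. `ascrep` takes per-population AIRR rearrangement tables (MiAIRR
TSV columns: `sequence_id`, `v_call`, `j_call`, `junction`, …) and computes
the repertoire readouts that answer that question, for immunologists and
computational biologists working with sorted-population AIRR-seq data.

## The method

1. **Clonal lineage assignment.** Rearrangements of one subject, pooled
   across populations, are partitioned by V gene, J gene, and junction
   length; within each group, lineages are the connected components of the
   graph linking junction pairs with nucleotide identity ≥ 0.85 (single
   linkage, inclusive threshold, exact integer arithmetic:
   `matches ≥ ⌈0.85·L⌉`).
2. **Clonality.** Per population, the rank-abundance profile: clones sorted
   by size with repertoire fractions f₁ ≥ f₂ ≥ … and their cumulative sum.
3. **Expanded clones.** With fractions in percent, the expanded set is
   ranks 1..r\*, where r\* is the deepest rank i whose consecutive drop
   f_i − f_{i+1} is ≥ 0.1 percentage points.
4. **Overlap.** Morisita-Horn index between populations A and B:
   MH = 2·Σpᵢqᵢ / (Σpᵢ² + Σqᵢ²) over lineage fractions p, q — exactly 0 for
   disjoint lineage sets, exactly 1 for identical fraction vectors.
5. **Connectivity.** The percent of a reference population's clones (all,
   expanded-only, or top-N) also detected in another population, plus
   sharing curves over a top-N grid and a Circos-style link table.
6. **SHM.** Per-population V-region mutation-count summaries and a
   per-lineage intraclonal-divergence check.

A synthetic-repertoire generator (`ascrep.synthetic_data`) produces
multi-population repertoires with heavy-tailed (Zipf) clone sizes, a
configurable lineage-sharing probability, within-lineage variants confined
to the 85% homology radius of their founder, and exact per-sequence ground
truth — so every pipeline stage is testable without any data download.
See `docs/methods.md` for the full model and its assumptions.

## Worked example

```python
from ascrep import (SimConfig, generate, validate_repertoire, assign_lineages,
                    rank_profile, detect_expanded, morisita_horn, connectivity,
                    truth_connectivity)

cfg = SimConfig(n_lineages=200, sequences_per_population=2000,
                sharing=0.4, seed=42)
res = generate(cfg)
reps = [validate_repertoire(r)[0] for r in res.repertoires]
table = assign_lineages(reps, threshold=0.85)

print("lineages:", table.n_lineages)
prof = rank_profile(table, "pop5")
print("pop5 top-3 fractions:", [round(float(f), 4) for f in prof.fractions[:3]])
print("pop5 expanded clones:", len(detect_expanded(prof, threshold_pp=0.1)))
print("MH(pop5,pop2) =", round(morisita_horn(table, "pop5", "pop2"), 4))
print("connectivity(pop5->pop2, all) = %.1f%%" % connectivity(table, "pop5", "pop2"))
print("truth connectivity           = %.1f%%" % truth_connectivity(res.truth, "pop5", "pop2"))
```

prints

```
lineages: 200
pop5 top-3 fractions: [0.3935, 0.142, 0.081]
pop5 expanded clones: 14
MH(pop5,pop2) = 0.0048
connectivity(pop5->pop2, all) = 41.9%
truth connectivity           = 41.9%
```

All 200 simulated lineages are recovered; the largest pop5 clone holds 39%
of the repertoire and the 0.1-pp drop rule delimits a 14-clone expanded
head. 41.9% of pop5's clones are also found in pop2 — exactly the
generator's realized sharing (configured probability 0.4) — while the
Morisita-Horn index is near 0 because the two populations' *abundance*
vectors are nearly uncorrelated even though many lineages are shared.

The same pipeline runs from the shell, on simulated or real tables:

```bash
ascrep run --out-dir out/ --seed 42              # simulate -> report.json
ascrep run --in pop2.tsv --in pop5.tsv --out-dir out/ --subject S1
ascrep simulate --n-lineages 200 --seed 7 --out-dir sim/
ascrep assign --in sim/pop2.tsv --in sim/pop5.tsv --threshold 0.85 --out-dir out/
```

`ascrep run` writes `lineages.tsv`, `clone_sizes.tsv`, `expanded.tsv`,
`overlap.tsv`, `connectivity.tsv`, `links.tsv`, `shm.tsv`,
`divergence.tsv`, and a `report.json` that records the resolved
configuration; identical configuration and seed reproduce it byte for byte.

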
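# Methods

## The problem

In systemic lupus erythematosus (SLE), circulating antibody-secreting cells
(ASCs) can be sorted by CD19 and CD138 into four populations spanning a
maturation gradient (pop2: CD19+CD138−, pop3: CD19+CD138+, pop4:
CD19−CD138−, pop5: CD19−CD138+). Whether these populations arise from
distinct precursors or from a common precursor maturing longitudinally is a
question the B-cell receptor repertoire can answer: if populations share
clonal lineages, they share precursors. `ascrep` implements the repertoire
computations needed to ask that question from AIRR-seq rearrangement tables —
clonal lineage assignment, clonality profiles, expanded-clone detection,
inter-population connectivity, Morisita overlap, and somatic-hypermutation
(SHM) summaries — together with a synthetic-repertoire generator that makes
every stage testable against exact ground truth.

## Clonal lineage assignment

A clonal lineage is the set of rearrangements inferred to descend from one
founding V(D)J recombination event. Two sequences can be clonally related
only if they carry the same V gene, the same J gene, and the same junction
(CDR3) length; within such a group, lineages are the connected components of
the graph linking every junction pair with nucleotide identity ≥ 0.85
(single linkage). Design choices, all surfaced as parameters:

- **Gene-level matching.** Raw annotations may carry allele suffixes
  (`IGHV1-69*01`) and multiple comma-separated calls; normalization keeps the
  first call (aligners list the best match first) and strips the allele.
  Allele calls are unstable under SHM, and clonal matching is a gene-level
  notion.
- **Homology substrate.** Identity is computed on the junction nucleotide
  string as provided (CDR3 plus anchors). Amino-acid homology is a
  plausible alternative the package does not implement; nucleotide identity
  is the stricter and more reproducible operationalization.
- **Single linkage.** Only a homology threshold is assumed; single linkage
  is the weakest clustering assumption consistent with it and the standard
  choice for B-cell clonal grouping.
- **Inclusive threshold, exact arithmetic.** Identity is the exact rational
  matches/length and the test is `matches >= ceil(0.85 * L)` in integer
  arithmetic, so a pair at exactly 85% links and no floating-point artifact
  can flip a boundary pair. 85% is read as attained-at-85 (≥, not >).
- **Joint, within-subject clustering.** All populations of one subject are
  pooled before clustering — connectivity between populations is only
  meaningful if a lineage id can span them — and subjects are never pooled.
- **Determinism.** Lineage ids are 1..K ordered by each lineage's
  lexicographically smallest member `sequence_id`, so labels are invariant
  under input permutation.

Within a V/J/length group, identical junctions are deduplicated and the
remaining unique junctions compared all-pairs with vectorized byte
comparisons feeding a union-find. All-pairs work is quadratic in unique
junctions per group, which is comfortable at the emulated sequencing depth
(~50,000 sequences per sample) because the V × J × length key space splits
the pool into many small groups.

## Repertoire statistics

- **Rank profile.** Clones of one population sorted by size descending
  (ties broken by lineage id), with fractions of the population total and
  their cumulative sum — the rank-abundance "clonality" curve.
  Clone size defaults to unique retained-sequence counts;
  duplicate-weighted sizes are computed alongside, since collapsing policy
  upstream is unknown.
- **Expanded clones.** With clone shares f1 ≥ f2 ≥ … in percent, a
  consecutive pair qualifies when f_i − f_{i+1} ≥ 0.1 percentage points.
  The expanded set is ranks 1..r* with r* the **deepest** (largest)
  qualifying index — the elbow reading of the rule; the alternative
  maximal-prefix reading is available via `rule="prefix"`. Only observed
  consecutive pairs are scanned (no phantom f_{n+1}=0), comparisons are done
  on exact rationals, and an empty set is possible.
- **Morisita-Horn overlap.** MH = 2·Σp_i q_i / (Σp_i² + Σq_i²) on lineage
  fraction vectors over the union of lineage sets: exactly 0 on disjoint
  supports, exactly 1 on identical fraction vectors (guaranteed by integer
  arithmetic on counts). The index is named "Morisita" in common usage; the
  Morisita-Horn form is the standard repertoire statistic bounded in [0,1],
  and the classical integer-count Morisita index is provided as an option.
- **Connectivity.** 100 × (scoped reference clones present in the other
  population) / (scoped reference clones), where scope is all clones, the
  expanded set, or the top-N by size. Presence means unique-sequence count
  > 0, so presence never depends on read-depth weighting. An empty scope
  (e.g. no expanded clones) yields a missing value, never 0 — coercing to 0
  would silently bias cohort summaries. Sharing curves evaluate top-N
  connectivity over a grid (default 5, 10, 25, 50, 100).
- **Link table.** One row per (lineage, population pair) with the lineage
  present in both, with both sizes — the input of a chord/Circos display.

## SHM summaries

V-region mutation counts come from the input column (annotated upstream by
the aligner) and are never recomputed. Per population: n, mean, median, and
interquartile range over sequences with non-missing counts; populations
without data are reported missing. Intraclonal divergence is assessed per
multi-member lineage as (i) the mean pairwise junction Hamming distance
(computed exactly in O(mL) by column-wise character counting) and (ii) the
within-lineage range of mutation counts; a lineage is flagged divergent when
the range exceeds a cutoff (default 5 mutations — a tool parameter, not a
biological constant; sequential accumulation of somatic mutation has no
formulaic definition, and the count range is the simplest monotone proxy).
Singleton lineages are excluded, not zero-filled.

## Synthetic data generator

The generator emulates multi-population ASC repertoires of one subject with
exact ground truth:

- **Lineages.** `n_lineages` founders (default 500 for desk-scale work),
  each with a key drawn from a built-in V/J catalog (allele suffixes
  included, one multi-call entry, uniform usage) and a junction length from
  multiples of 3 in 30–66 nt. Founders sharing a key are rejection-sampled
  to pairwise identity < 0.70.
- **Sharing.** A global probability `s`: per lineage, i.i.d. Bernoulli(s)
  membership per population, rejecting all-absent draws (s = 0 degenerates
  to one uniform home population). Conditional on membership in a reference
  population, membership elsewhere remains Bernoulli(s), so true pairwise
  connectivity is 100·s in expectation — the property the recovery tests
  exploit. Alternatively a home-population sharing matrix M, where a
  lineage homed in population i is shared into j with probability M[i][j].
- **Clone sizes.** Per population, each member lineage gets one guaranteed
  sequence and the remaining depth (default 50,000 per population, scaled
  down in tests) is multinomial over Zipf weights rank^(−α), α = 1.5, with
  ranks assigned by a per-population shuffle — a heavy-tailed size law whose
  realized log-log head slope tracks −α. The guaranteed seat makes
  configured and realized membership coincide, keeping the truth table an
  exact oracle.
- **Variants.** Each sequence mutates up to floor(0.075·L) positions of its
  founder, so within-lineage pairs sit at identity ≥ 1 − 2·0.075 = 0.85
  (at or above the clustering threshold) while cross-lineage same-key pairs
  stay below ≈ 0.78 — a deliberate dead zone around the threshold that makes
  lineage recovery unambiguous and lets tests demand *exact* label recovery.
  `adversarial_pair()` separately constructs pairs at exactly 0.85/0.84 to
  probe the boundary rule itself.
- **Counts.** duplicate_count = 1 + Poisson(0.3); v_mutation_count =
  Poisson(shm_lambda, default 8, drawn once per lineage) plus a rounded
  Normal(0, shm_jitter) per sequence floored at 0. shm_jitter = 0 (the
  default, "zero-jitter mode") gives every lineage a mutation-count range of
  0, the negative control for the divergence flag.
- **Corruption.** `inject_corruption()` damages a fraction of rows (N
  injection, emptied junctions) to exercise validation.

Everything derives from one `numpy` generator seeded by `SimConfig.seed`;
identical config + seed give byte-identical output files.

What the generator does **not** emulate: real V(D)J recombination, indels,
realistic gene-usage frequencies, sequencing error inside the junction,
allelic ambiguity beyond the catalog, or clone-size correlation across
populations. Passing recovery tests therefore shows the pipeline implements
its stated rules exactly, not that those rules are optimal on noisy real
repertoires where identity margins are not guaranteed.

## Problem sizes and numerical choices

Test and benchmark runs use scaled-down conditions chosen for quick,
repeatable desk-scale execution: recovery sweeps use 500 lineages, 4
populations, and 1,200 sequences per population over 20 seeds per sharing
level; unit fixtures use 40–120 lineages and a few hundred sequences per
population. Threshold comparisons (0.85 identity, 0.1 pp drop) are exact
rationals end to end; reported percentages are doubles rounded only at
output. Degenerate inputs are errors, not silent defaults: empty
repertoires, mixed subjects, unknown populations, empty connectivity scopes.

## Known limitations

- Nucleotide (not amino-acid) CDR3 homology; no indel-tolerant comparison —
  junctions of different lengths can never be clonally related here.
- The expanded-set rule admits two readings (deepest qualifying drop vs
  maximal qualifying prefix); both are implemented but the deepest-drop
  reading is the default and the two can disagree on profiles with multiple
  deep drops.
- SHM divergence uses mutation-count ranges, not lineage-tree topology; it
  can miss convergent mutation patterns with equal counts.
- The classical Morisita index is undefined for populations of fewer than
  two sequences.
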
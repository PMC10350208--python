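"""Clonality, expansion, overlap, and connectivity statistics."""

import numpy as np
import pandas as pd
import pytest

from ascrep import (
    assign_lineages,
    connectivity,
    detect_expanded,
    link_table,
    morisita,
    morisita_horn,
    overlap_matrix,
    rank_profile,
    sharing_curve,
    top_clone_composition,
)
from ascrep.lineage import LineageTable
from ascrep.repstats import RankedCloneProfile
from conftest import make_repertoire


def table_from_sizes(sizes_by_pop, subject="S1"):
    """LineageTable straight from {pop: {lineage_id: n_seq}} count dicts."""
    assign_rows, size_rows = [], []
    for pop, sizes in sizes_by_pop.items():
        for lid, n in sizes.items():
            size_rows.append({"lineage_id": lid, "population": pop,
                              "n_seq": n, "n_dup": n})
            for k in range(n):
                assign_rows.append({
                    "sequence_id": f"{pop}_{lid}_{k}", "subject": subject,
                    "population": pop, "lineage_id": lid, "v_gene": "IGHV1-69",
                    "j_gene": "IGHJ4", "junction_length": 30, "junction": "A" * 30,
                    "duplicate_count": 1, "v_mutation_count": np.nan,
                })
    return LineageTable(subject=subject,
                        assignments=pd.DataFrame(assign_rows),
                        sizes=pd.DataFrame(size_rows))


def profile_from_sizes(sizes, population="pop5"):
    order = sorted(range(len(sizes)), key=lambda i: (-sizes[i], i))
    return RankedCloneProfile(
        population=population,
        lineage_ids=[i + 1 for i in order],
        sizes=[sizes[i] for i in order],
        total=sum(sizes),
    )


class TestRankProfile:
    def test_fractions_and_cumulative(self):
        table = table_from_sizes({"pop2": {1: 6, 2: 3, 3: 1}})
        prof = rank_profile(table, "pop2")
        assert prof.sizes == [6, 3, 1]
        assert prof.fractions == pytest.approx([0.6, 0.3, 0.1])
        assert prof.cumulative == pytest.approx([0.6, 0.9, 1.0])

    def test_single_lineage(self):
        prof = rank_profile(table_from_sizes({"pop2": {7: 4}}), "pop2")
        assert list(prof.fractions) == [1.0]

    def test_ties_broken_by_lineage_id(self):
        prof = rank_profile(table_from_sizes({"pop2": {3: 2, 1: 2, 2: 2}}), "pop2")
        assert prof.lineage_ids == [1, 2, 3]

    def test_unknown_population(self):
        with pytest.raises(ValueError):
            rank_profile(table_from_sizes({"pop2": {1: 1}}), "popX")


class TestTopCloneComposition:
    def test_absent_reference_clone_is_zero(self):
        table = table_from_sizes({"pop5": {1: 5, 2: 5}, "pop2": {2: 10}})
        comp = top_clone_composition(
            rank_profile(table, "pop2"), rank_profile(table, "pop5"), n_top=2
        )
        by_lid = comp.set_index("lineage_id")["fraction"]
        assert by_lid[1] == 0.0
        assert by_lid[2] == 1.0

    def test_self_comparison_returns_own_fractions(self):
        table = table_from_sizes({"pop5": {1: 6, 2: 3, 3: 1}})
        prof = rank_profile(table, "pop5")
        comp = top_clone_composition(prof, prof, n_top=3)
        assert comp["fraction"][:3].tolist() == pytest.approx([0.6, 0.3, 0.1])
        assert comp["fraction"].sum() == pytest.approx(1.0)  # remainder closes mass


class TestDetectExpanded:
    def test_deepest_qualifying_drop_sets_boundary(self):
        # percents (2.0, 1.5, 1.0, 0.95, 0.1): drops (0.5, 0.5, 0.05, 0.85),
        # then 0.095 into the uniform tail (below threshold) and 0 thereafter
        prof = profile_from_sizes([2000, 1500, 1000, 950, 100] + [5] * 18890)
        assert prof.total == 100_000
        exp = detect_expanded(prof, threshold_pp=0.1)
        assert exp.boundary_rank == 4
        assert exp.lineage_ids == prof.lineage_ids[:4]

    def test_uniform_profile_has_empty_set(self):
        prof = profile_from_sizes([1] * 10_000)
        exp = detect_expanded(prof, threshold_pp=0.1)
        assert exp.boundary_rank == 0 and len(exp) == 0

    def test_single_dominant_clone(self):
        # percents (50.0, 0.05 x 1000): only the first drop qualifies
        prof = profile_from_sizes([50_000] + [50] * 1000)
        exp = detect_expanded(prof, threshold_pp=0.1)
        assert exp.boundary_rank == 1

    def test_drop_exactly_at_threshold_qualifies(self):
        # drop of exactly 0.1pp between ranks 1 and 2, flat tail after
        prof = profile_from_sizes([20] + [10] * 998)
        assert prof.total == 10_000
        assert detect_expanded(prof, threshold_pp=0.1).boundary_rank == 1
        prof2 = profile_from_sizes([19] + [10] * 998)  # 0.090pp: below
        assert detect_expanded(prof2, threshold_pp=0.1).boundary_rank == 0

    def test_prefix_rule_stops_at_first_failing_drop(self):
        prof = profile_from_sizes([2000, 1500, 1000, 950, 100] + [5] * 18890)
        exp = detect_expanded(prof, threshold_pp=0.1, rule="prefix")
        assert exp.boundary_rank == 2

    def test_output_is_rank_prefix(self, small_table):
        for pop in small_table.populations:
            prof = rank_profile(small_table, pop)
            exp = detect_expanded(prof)
            assert exp.lineage_ids == prof.lineage_ids[: exp.boundary_rank]


class TestMorisita:
    def test_identical_repertoires_exactly_one(self):
        sizes = {1: 700, 2: 200, 3: 100}
        table = table_from_sizes({"pop2": sizes, "pop3": dict(sizes)})
        assert morisita_horn(table, "pop2", "pop3") == 1.0

    def test_disjoint_repertoires_exactly_zero(self):
        table = table_from_sizes({"pop2": {1: 5, 2: 5}, "pop3": {3: 5, 4: 5}})
        assert morisita_horn(table, "pop2", "pop3") == 0.0

    def test_hand_computed_value(self):
        # p=(0.5, 0.5, 0), q=(1, 0, 0) -> 2*0.5 / (0.5 + 1.0) = 2/3
        table = table_from_sizes({"pop2": {1: 5, 2: 5}, "pop3": {1: 10}})
        assert morisita_horn(table, "pop2", "pop3") == pytest.approx(2 / 3)

    def test_symmetric_and_bounded(self, small_table):
        pops = small_table.populations
        for a in pops:
            for b in pops:
                if a >= b:
                    continue
                v1 = morisita_horn(small_table, a, b)
                v2 = morisita_horn(small_table, b, a)
                assert v1 == v2
                assert 0.0 <= v1 <= 1.0

    def test_classical_morisita_near_one_on_copy(self):
        sizes = {1: 700, 2: 200, 3: 100}
        table = table_from_sizes({"pop2": sizes, "pop3": dict(sizes)})
        assert morisita(table, "pop2", "pop3") == pytest.approx(1.0, abs=0.01)

    def test_overlap_matrix_shape(self, small_table):
        mat = overlap_matrix(small_table)
        pops = small_table.populations
        assert list(mat.columns) == pops
        assert all(mat.loc[p, p] == 1.0 for p in pops)
        assert np.allclose(mat.values, mat.values.T)


class TestConnectivity:
    def test_full_containment_is_100(self):
        table = table_from_sizes({"pop5": {1: 3, 2: 2}, "pop2": {1: 1, 2: 1, 3: 9}})
        assert connectivity(table, "pop5", "pop2") == 100.0

    def test_disjoint_is_0(self):
        table = table_from_sizes({"pop5": {1: 3}, "pop2": {2: 3}})
        assert connectivity(table, "pop5", "pop2") == 0.0

    def test_empty_expanded_scope_is_missing(self):
        table = table_from_sizes({"pop5": {i: 1 for i in range(1, 50)},
                                  "pop2": {1: 1}})
        assert connectivity(table, "pop5", "pop2", scope="expanded") is None

    def test_expanded_scope_counts_only_head(self):
        # pop5: one dominant clone (shared) + uniform tail (unshared)
        sizes5 = {1: 600}
        sizes5.update({i: 1 for i in range(2, 402)})
        table = table_from_sizes({"pop5": sizes5, "pop2": {1: 5}})
        assert connectivity(table, "pop5", "pop2", scope="expanded") == 100.0
        assert connectivity(table, "pop5", "pop2", scope="all") < 1.0

    def test_bounded(self, small_table):
        pops = small_table.populations
        for ref in pops:
            for other in pops:
                if ref == other:
                    continue
                pct = connectivity(small_table, ref, other)
                assert 0.0 <= pct <= 100.0


class TestSharingCurve:
    def test_top1_shared_top2_not(self):
        table = table_from_sizes({"pop5": {1: 5, 2: 3}, "pop2": {1: 2}})
        curve = sharing_curve(table, "pop5", ["pop2"], n_grid=[1, 2])
        assert curve["percent"].tolist() == [100.0, 50.0]

    def test_self_sharing_always_100(self):
        table = table_from_sizes({"pop5": {1: 5, 2: 3, 3: 2}, "pop2": {9: 1}})
        curve = sharing_curve(table, "pop5", ["pop5"], n_grid=[1, 2, 3])
        assert curve["percent"].tolist() == [100.0, 100.0, 100.0]

    def test_n_beyond_available_flagged(self):
        table = table_from_sizes({"pop5": {1: 5, 2: 3}, "pop2": {1: 2}})
        curve = sharing_curve(table, "pop5", ["pop2"], n_grid=[1, 25])
        assert curve.loc[curve["n"] == 25, "n_available"].item() == 2


class TestLinkTable:
    def test_one_shared_lineage_one_link(self):
        table = table_from_sizes({"pop2": {1: 4}, "pop3": {1: 2}})
        links = link_table(table)
        assert len(links) == 1
        row = links.iloc[0]
        assert (row["source_pop"], row["target_pop"]) == ("pop2", "pop3")
        assert (row["size_source"], row["size_target"]) == (4, 2)

    def test_lineage_in_three_pops_gives_three_links(self):
        table = table_from_sizes({"pop2": {1: 1}, "pop3": {1: 1}, "pop4": {1: 1}})
        assert len(link_table(table)) == 3

    def test_disjoint_populations_empty(self):
        table = table_from_sizes({"pop2": {1: 1}, "pop3": {2: 1}})
        assert len(link_table(table)) == 0
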
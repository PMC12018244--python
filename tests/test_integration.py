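import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evmeth.integration import (
    CommonGenes,
    common_genes,
    concordance_class,
    cross_dmg_deg,
    gene_sets_from_partition_counts,
    venn_by_stratum,
    venn_counts,
)

GROUPS = ("a", "b", "c")

# Worked three-group example: exclusive multi-group cell cardinalities per
# (region class, direction) stratum.  Strata use disjoint gene universes, so
# the distinct common-gene total is the plain sum of the >=2-group cells:
# hypo 8+16+1+1 + 22+4+34+7 = 93, hyper 2+1 + 2+1+7 = 13, together 106;
# triples alone 8+22 = 30.
WORKED_CELLS = {
    ("promoter", "hypo"): {("a", "b", "c"): 8, ("a", "c"): 16, ("a", "b"): 1, ("b", "c"): 1},
    ("body", "hypo"): {("a", "b", "c"): 22, ("a", "b"): 4, ("a", "c"): 34, ("b", "c"): 7},
    ("promoter", "hyper"): {("a", "b", "c"): 0, ("a", "b"): 2, ("b", "c"): 0, ("a", "c"): 1},
    ("body", "hyper"): {("a", "b", "c"): 0, ("a", "b"): 2, ("b", "c"): 1, ("a", "c"): 7},
}
# exclusive singletons; they must never influence common-gene totals
WORKED_SINGLES = {("a",): 40, ("b",): 25, ("c",): 60}


def build_worked_partitions():
    partitions = {}
    for stratum, cells in WORKED_CELLS.items():
        counts = dict(cells)
        counts.update(WORKED_SINGLES)
        prefix = f"{stratum[0][:4].upper()}_{stratum[1][:4].upper()}_"
        sets = gene_sets_from_partition_counts(counts, GROUPS, prefix=prefix)
        partitions[stratum] = venn_counts(sets)
    return partitions


class TestVennCounts:
    def test_three_empty_sets(self):
        part = venn_counts({g: set() for g in GROUPS})
        assert part.cells == {}

    def test_single_shared_gene(self):
        part = venn_counts({g: {"G1"} for g in GROUPS})
        assert part.cell("a", "b", "c") == {"G1"}
        assert sum(part.cardinalities().values()) == 1

    def test_enumerated_memberships(self):
        part = venn_counts({"a": {"G1", "G2"}, "b": {"G2", "G3"}, "c": {"G2"}})
        assert part.cell("a") == {"G1"}
        assert part.cell("b") == {"G3"}
        assert part.cell("a", "b", "c") == {"G2"}
        assert part.cell("a", "b") == frozenset()

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            venn_counts({"a": {"G1"}})

    @given(
        st.dictionaries(
            st.sampled_from(GROUPS),
            st.sets(st.integers(0, 30).map(lambda i: f"G{i}"), max_size=15),
            min_size=2,
            max_size=3,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_partition_round_trip_and_disjointness(self, sets):
        part = venn_counts(sets)
        # cells are pairwise disjoint and reconstruct the inputs exactly
        all_genes = [g for cell in part.cells.values() for g in cell]
        assert len(all_genes) == len(set(all_genes))
        rebuilt = part.to_group_sets()
        assert {g: set(v) for g, v in sets.items()} == rebuilt

    def test_group_order_invariance(self):
        sets = {"a": {"G1", "G2"}, "b": {"G2"}, "c": {"G1", "G3"}}
        p1 = venn_counts(sets)
        p2 = venn_counts(dict(reversed(list(sets.items()))))
        assert p1.cells == p2.cells


class TestCommonGenes:
    def test_worked_example_totals(self):
        """Cells 8/16/1/1, 22/4/34/7, 0/2/0/1, 0/2/1/7 -> 106 = 93 hypo + 13 hyper."""
        common = common_genes(build_worked_partitions(), min_groups=2)
        assert common.n_distinct == 106
        assert common.distinct_by_direction() == {"hyper": 13, "hypo": 93}

    def test_worked_example_triples_only(self):
        common = common_genes(build_worked_partitions(), min_groups=3)
        assert common.n_distinct == 30  # 8 promoter-hypo + 22 body-hypo
        assert common.distinct_by_direction() == {"hypo": 30}

    def test_all_singletons_empty(self):
        sets = {"a": {"G1"}, "b": {"G2"}, "c": {"G3"}}
        part = venn_counts(sets)
        assert common_genes({("body", "hypo"): part}).table.empty

    def test_min_groups_monotone(self):
        parts = build_worked_partitions()
        assert common_genes(parts, 3).n_distinct <= common_genes(parts, 2).n_distinct

    def test_min_groups_below_two_rejected(self):
        with pytest.raises(ValueError):
            common_genes(build_worked_partitions(), min_groups=1)

    def test_venn_by_stratum_matches_manual_partition(self):
        dmg = pd.DataFrame(
            [
                ("a", "G1", "body", "hypo"),
                ("b", "G1", "body", "hypo"),
                ("c", "G1", "body", "hypo"),
                ("a", "G2", "promoter", "hyper"),
                ("b", "G2", "promoter", "hyper"),
            ],
            columns=["group", "gene", "region_class", "direction"],
        )
        parts = venn_by_stratum(dmg)
        assert parts[("body", "hypo")].cell("a", "b", "c") == {"G1"}
        assert parts[("promoter", "hyper")].cell("a", "b") == {"G2"}


class TestCrossDmgDeg:
    def common_table(self, rows):
        return CommonGenes(
            table=pd.DataFrame(
                rows, columns=["gene", "region_class", "direction", "groups", "n_groups"]
            ),
            min_groups=2,
        )

    def degs(self, rows):
        return pd.DataFrame(rows, columns=["gene", "direction", "adj_p"])

    def test_body_hypo_up_class(self):
        """Body hypo-methylation with up-regulation: the activation pattern."""
        result = cross_dmg_deg(
            self.common_table([("DSE", "body", "hypo", "a,c", 2)]),
            self.degs([("DSE", "up", 0.001)]),
        )
        assert result.table.at[0, "concordance_class"] == "body-hypo/up"

    def test_promoter_hypo_down_class(self):
        result = cross_dmg_deg(
            self.common_table([("SLA", "promoter", "hypo", "a,b", 2)]),
            self.degs([("SLA", "down", 0.01)]),
        )
        assert result.table.at[0, "concordance_class"] == "promoter-hypo/down"

    def test_unnamed_pattern_is_other(self):
        assert concordance_class("body", "hyper", "up") == "other"
        assert concordance_class("promoter", "hyper", "down") == "promoter-hyper/down"

    def test_disjoint_universes_empty(self):
        result = cross_dmg_deg(
            self.common_table([("G1", "body", "hypo", "a,b", 2)]),
            self.degs([("G2", "up", 0.001)]),
        )
        assert result.table.empty

    def test_non_significant_deg_excluded(self):
        result = cross_dmg_deg(
            self.common_table([("G1", "body", "hypo", "a,b", 2)]),
            self.degs([("G1", "up", 0.2)]),
            alpha=0.05,
        )
        assert result.table.empty

    def test_conflicting_directions_reported_not_joined(self):
        result = cross_dmg_deg(
            self.common_table([("G1", "body", "hypo", "a,b", 2)]),
            self.degs([("G1", "up", 0.001), ("G1", "down", 0.002)]),
        )
        assert result.conflicts == ["G1"]
        assert result.table.empty

    def test_gene_in_two_strata_yields_two_rows(self):
        result = cross_dmg_deg(
            self.common_table(
                [
                    ("G1", "body", "hypo", "a,b", 2),
                    ("G1", "promoter", "hypo", "a,c", 2),
                ]
            ),
            self.degs([("G1", "up", 0.001)]),
        )
        assert len(result.table) == 2
        assert result.n_genes == 1


class TestGeneSetsFromPartitionCounts:
    def test_realizes_requested_cells(self):
        counts = {("a",): 3, ("a", "b"): 2, ("a", "b", "c"): 1}
        sets = gene_sets_from_partition_counts(counts, GROUPS)
        card = venn_counts(sets).cardinalities()
        assert card[frozenset({"a"})] == 3
        assert card[frozenset({"a", "b"})] == 2
        assert card[frozenset({"a", "b", "c"})] == 1

    def test_invalid_cells_rejected(self):
        with pytest.raises(ValueError):
            gene_sets_from_partition_counts({("z",): 1}, GROUPS)
        with pytest.raises(ValueError):
            gene_sets_from_partition_counts({("a",): -1}, GROUPS)
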
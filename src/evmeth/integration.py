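"""Multi-group intersection of dmGs and crossing with expression calls.

Per-group dmG lists are intersected within each (region class, direction)
stratum into an exact exclusive Venn partition; "common" genes are those
whose membership spans at least ``min_groups`` groups in some stratum.
Common genes are then joined against a differential-expression table
(adjusted p below alpha) and classified by the concordance between their
methylation change and expression direction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

CONCORDANCE_CLASSES = (
    "promoter-hypo/up",
    "promoter-hypo/down",
    "promoter-hyper/down",
    "body-hypo/up",
    "body-hypo/down",
    "other",
)


@dataclass(frozen=True)
class VennPartition:
    """Exclusive-cell partition of per-group gene sets.

    ``cells`` maps each non-empty subset of group names (frozenset) to the
    genes whose group membership is exactly that subset.  Cells are pairwise
    disjoint and their union is the union of the input sets.
    """

    group_names: tuple[str, ...]
    cells: Mapping[frozenset, frozenset]

    def cell(self, *groups: str) -> frozenset:
        return self.cells.get(frozenset(groups), frozenset())

    def cardinalities(self) -> dict[frozenset, int]:
        return {k: len(v) for k, v in self.cells.items()}

    def to_group_sets(self) -> dict[str, set]:
        """Reconstruct the per-group input sets (exact round trip)."""
        out: dict[str, set] = {g: set() for g in self.group_names}
        for subset, genes in self.cells.items():
            for g in subset:
                out[g].update(genes)
        return out

    def to_json_dict(self) -> dict:
        return {
            ",".join(sorted(subset)): sorted(genes)
            for subset, genes in sorted(
                self.cells.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
            )
        }


def venn_counts(per_group_gene_sets: Mapping[str, Iterable[str]]) -> VennPartition:
    """Exact exclusive Venn partition of >= 2 named gene sets."""
    if len(per_group_gene_sets) < 2:
        raise ValueError("at least 2 groups are required for an intersection")
    sets = {g: set(v) for g, v in per_group_gene_sets.items()}
    names = tuple(sets)
    cells: dict[frozenset, set] = {}
    for gene in set().union(*sets.values()):
        membership = frozenset(g for g, s in sets.items() if gene in s)
        cells.setdefault(membership, set()).add(gene)
    return VennPartition(
        group_names=names,
        cells={k: frozenset(v) for k, v in cells.items()},
    )


def venn_by_stratum(dmgenes: pd.DataFrame) -> dict[tuple[str, str], VennPartition]:
    """One VennPartition per (region_class, direction) stratum of a dmG table.

    Groups absent from a stratum contribute empty sets so every partition
    spans the same group universe.
    """
    groups = sorted(dmgenes["group"].unique())
    out = {}
    for (region_class, direction), sub in dmgenes.groupby(
        ["region_class", "direction"], sort=True
    ):
        per_group = {g: set(sub.loc[sub["group"] == g, "gene"]) for g in groups}
        out[(region_class, direction)] = venn_counts(per_group)
    return out


@dataclass
class CommonGenes:
    """Genes common to >= min_groups groups, pooled over strata.

    ``table`` has one row per (gene, region_class, direction) stratum record;
    a gene common in several strata keeps all its records but counts once in
    ``n_distinct``.
    """

    table: pd.DataFrame  # gene, region_class, direction, groups, n_groups
    min_groups: int

    @property
    def n_distinct(self) -> int:
        return self.table["gene"].nunique()

    def distinct_by_direction(self) -> dict[str, int]:
        return {
            d: self.table.loc[self.table["direction"] == d, "gene"].nunique()
            for d in sorted(self.table["direction"].unique())
        }

    def genes(self) -> set[str]:
        return set(self.table["gene"])


def common_genes(
    partitions: Mapping[tuple[str, str], VennPartition], min_groups: int = 2
) -> CommonGenes:
    """Pool Venn cells of subset size >= min_groups across all strata."""
    if min_groups < 2:
        raise ValueError("min_groups must be >= 2")
    rows = []
    for (region_class, direction), part in partitions.items():
        for subset, genes in part.cells.items():
            if len(subset) >= min_groups:
                for gene in sorted(genes):
                    rows.append(
                        (
                            gene,
                            region_class,
                            direction,
                            ",".join(sorted(subset)),
                            len(subset),
                        )
                    )
    table = pd.DataFrame(
        rows, columns=["gene", "region_class", "direction", "groups", "n_groups"]
    ).sort_values(["gene", "region_class", "direction"], ignore_index=True)
    return CommonGenes(table=table, min_groups=min_groups)


def concordance_class(
    region_class: str, meth_direction: str, expr_direction: str
) -> str:
    """Named methylation/expression concordance pattern, else ``"other"``."""
    label = f"{region_class}-{meth_direction}/{expr_direction}"
    return label if label in CONCORDANCE_CLASSES else "other"


@dataclass
class IntegrationResult:
    """dmG x deG join with concordance classes and excluded conflicts."""

    table: pd.DataFrame
    conflicts: list[str] = field(default_factory=list)

    def class_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(CONCORDANCE_CLASSES, 0)
        counts.update(self.table["concordance_class"].value_counts().to_dict())
        return counts

    @property
    def n_genes(self) -> int:
        return self.table["gene"].nunique()


def cross_dmg_deg(
    common: CommonGenes | pd.DataFrame,
    degs: pd.DataFrame,
    alpha: float = 0.05,
) -> IntegrationResult:
    """Join common dmGs with significant deGs on gene symbol.

    deGs are filtered to adjusted p < alpha.  Gene symbols that occur in the
    deG table with conflicting expression directions are reported as
    conflicts and excluded from the join, never silently resolved.  A gene
    common in two methylation strata yields two rows.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    table = common.table if isinstance(common, CommonGenes) else common
    sig = degs.loc[degs["adj_p"] < alpha, ["gene", "direction", "adj_p"]]
    dir_counts = sig.groupby("gene")["direction"].nunique()
    conflicts = sorted(dir_counts.index[dir_counts > 1])
    sig = sig[~sig["gene"].isin(conflicts)].drop_duplicates("gene")
    merged = table.merge(
        sig.rename(columns={"direction": "expr_direction"}), on="gene", how="inner"
    ).rename(columns={"direction": "meth_direction"})
    merged["concordance_class"] = [
        concordance_class(r, m, e)
        for r, m, e in zip(
            merged["region_class"], merged["meth_direction"], merged["expr_direction"]
        )
    ]
    cols = [
        "gene",
        "region_class",
        "meth_direction",
        "expr_direction",
        "adj_p",
        "concordance_class",
    ]
    return IntegrationResult(
        table=merged[cols].sort_values(["gene", "region_class"], ignore_index=True),
        conflicts=conflicts,
    )


def gene_sets_from_partition_counts(
    cell_counts: Mapping[frozenset | tuple, int],
    groups: Iterable[str],
    prefix: str = "G",
) -> dict[str, set]:
    """Build per-group gene sets realizing given exclusive-cell cardinalities.

    Useful for reconstructing published Venn-diagram arithmetic: synthetic
    gene symbols are minted per cell so the exclusive partition of the
    returned sets has exactly the requested counts.
    """
    groups = list(groups)
    out: dict[str, set] = {g: set() for g in groups}
    counter = itertools.count()
    for subset, n in sorted(
        cell_counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
    ):
        subset = frozenset(subset)
        if not subset or not subset <= set(groups):
            raise ValueError(f"cell {sorted(subset)} is not a subset of the groups")
        if n < 0:
            raise ValueError("cell counts must be non-negative")
        for _ in range(n):
            gene = f"{prefix}{next(counter):05d}"
            for g in subset:
                out[g].add(gene)
    return out
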
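"""Gene/region projection of differentially methylated CpGs.

Illumina manifests annotate each probe with zero or more ``GENE:RegionGroup``
pairs (UCSC RefGene) and one relation to the nearest CpG island.  This module
collapses probe-level calls onto genes, splitting the RefGene region groups
into two functional classes:

* **promoter** — TSS200, TSS1500, 5'UTR
* **body** — 1stExon, Body, 3'UTR, ExonBnd

A differentially methylated gene (dmG) record is one unique
(group, gene, region class, direction) with its supporting probes.  Opposite
directions for the same gene are kept as separate records; no aggregation
rule is applied across probes of conflicting sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

REGION_GROUPS = frozenset(
    {"TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR", "ExonBnd"}
)
PROMOTER_GROUPS = frozenset({"TSS200", "TSS1500", "5'UTR"})
BODY_GROUPS = frozenset({"1stExon", "Body", "3'UTR", "ExonBnd"})
ISLAND_RELATIONS = frozenset(
    {"Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea"}
)


def parse_region_group(region_label: str) -> str:
    """Classify a RefGene region group label as ``"promoter"`` or ``"body"``.

    Raises ``ValueError`` for labels outside the manifest vocabulary; there is
    deliberately no silent default.
    """
    if region_label in PROMOTER_GROUPS:
        return "promoter"
    if region_label in BODY_GROUPS:
        return "body"
    raise ValueError(
        f"unknown region group {region_label!r}; expected one of "
        f"{sorted(REGION_GROUPS)}"
    )


def parse_gene_region(field: str) -> list[tuple[str, str]]:
    """Parse a manifest ``gene_region`` field into (gene, region group) pairs.

    The field is a semicolon-separated list of ``GENE:RegionGroup`` entries;
    an empty field means an intergenic probe.
    """
    if field is None or (isinstance(field, float) and pd.isna(field)) or field == "":
        return []
    pairs = []
    for token in str(field).split(";"):
        token = token.strip()
        if not token:
            continue
        gene, sep, region = token.partition(":")
        if not sep or not gene or not region:
            raise ValueError(f"malformed gene_region token {token!r}")
        if region not in REGION_GROUPS:
            raise ValueError(f"unknown region group {region!r} in {token!r}")
        pairs.append((gene, region))
    return pairs


def _check_probes_in_manifest(dmcpgs: pd.DataFrame, manifest: pd.DataFrame) -> None:
    missing = set(dmcpgs["probe_id"]) - set(manifest.index)
    if missing:
        raise ValueError(
            f"{len(missing)} dmCpG probe(s) absent from manifest, e.g. "
            f"{sorted(missing)[:5]}"
        )


@dataclass
class GeneMappingResult:
    """dmG table plus the per-group count of intergenic probes dropped."""

    dmgenes: pd.DataFrame  # group, gene, region_class, direction, n_probes, probe_ids
    n_dropped_intergenic: dict[str, int]


def map_dmcpgs_to_genes(
    dmcpgs: pd.DataFrame, manifest: pd.DataFrame
) -> GeneMappingResult:
    """Project dmCpGs onto dmG records.

    Parameters
    ----------
    dmcpgs : DataFrame with at least ``probe_id``, ``group``, ``direction``.
    manifest : DataFrame indexed by probe_id with a ``gene_region`` column.

    Every (gene, region group) annotation of every dmCpG contributes to the
    record keyed by (group, gene, region class, direction); duplicates
    collapse with supporting-probe accumulation.  Probes with no gene
    annotation are dropped and counted per group.
    """
    _check_probes_in_manifest(dmcpgs, manifest)
    rows = []
    dropped: dict[str, int] = {}
    for rec in dmcpgs.itertuples(index=False):
        pairs = parse_gene_region(manifest.at[rec.probe_id, "gene_region"])
        if not pairs:
            dropped[rec.group] = dropped.get(rec.group, 0) + 1
            continue
        # a probe annotated twice to the same (gene, class) counts once
        seen = set()
        for gene, region in pairs:
            key = (rec.group, gene, parse_region_group(region), rec.direction)
            if key in seen:
                continue
            seen.add(key)
            rows.append(key + (rec.probe_id,))
    if rows:
        long = pd.DataFrame(
            rows, columns=["group", "gene", "region_class", "direction", "probe_id"]
        ).drop_duplicates()
        dmg = (
            long.groupby(["group", "gene", "region_class", "direction"], sort=True)[
                "probe_id"
            ]
            .agg(lambda s: sorted(set(s)))
            .reset_index()
        )
        dmg["n_probes"] = dmg["probe_id"].map(len)
        dmg["probe_ids"] = dmg["probe_id"].map(",".join)
        dmg = dmg.drop(columns="probe_id")
    else:
        dmg = pd.DataFrame(
            columns=["group", "gene", "region_class", "direction", "n_probes", "probe_ids"]
        )
    return GeneMappingResult(dmgenes=dmg, n_dropped_intergenic=dropped)


@dataclass
class IslandRegionTally:
    """Direction-stratified tallies of dmCpGs over genomic context.

    ``island`` counts each probe once by its island relation.  ``region_raw``
    counts every (probe, region group) annotation, so its marginals can
    exceed the dmCpG count when probes carry multiple annotations;
    ``region_unique`` counts each probe at most once per region group.
    """

    island: pd.DataFrame  # group, direction, island_relation, n
    region_raw: pd.DataFrame  # group, direction, region_group, n
    region_unique: pd.DataFrame


def island_relation_summary(
    dmcpgs: pd.DataFrame, manifest: pd.DataFrame
) -> IslandRegionTally:
    """Tally dmCpGs by direction x island relation and direction x region group."""
    _check_probes_in_manifest(dmcpgs, manifest)
    island_rows, raw_rows, uniq_rows = [], [], []
    for rec in dmcpgs.itertuples(index=False):
        rel = manifest.at[rec.probe_id, "island_relation"]
        if rel not in ISLAND_RELATIONS:
            raise ValueError(f"unknown island relation {rel!r} for {rec.probe_id}")
        island_rows.append((rec.group, rec.direction, rel))
        regions = [r for _, r in parse_gene_region(manifest.at[rec.probe_id, "gene_region"])]
        raw_rows.extend((rec.group, rec.direction, r) for r in regions)
        uniq_rows.extend((rec.group, rec.direction, r) for r in sorted(set(regions)))

    def tally(rows: list, col: str) -> pd.DataFrame:
        if not rows:
            return pd.DataFrame(columns=["group", "direction", col, "n"])
        df = pd.DataFrame(rows, columns=["group", "direction", col])
        return df.value_counts().rename("n").reset_index().sort_values(
            ["group", "direction", col], ignore_index=True
        )

    return IslandRegionTally(
        island=tally(island_rows, "island_relation"),
        region_raw=tally(raw_rows, "region_group"),
        region_unique=tally(uniq_rows, "region_group"),
    )
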
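"""Model/results surface over the paired differential-methylation analysis.

``PairedMethylationModel`` bundles a filtered beta matrix, a paired design
and (optionally) a probe manifest; ``fit()`` runs the per-group
npCV -> upper-quartile -> delta-beta calling and, when annotation is
available, the gene projection and multi-group intersection, returning a
``PairedMethylationResults`` with the calls, tallies and a ``summary()``
table.  Expression integration and over-representation hang off the results
object.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import annotation as ann
from . import integration as integ
from .calling import DmCallResult, ParameterSet, call_dmcpgs
from .enrichment import EnrichmentResult, GeneSetCollection, ora
from .io import read_beta_tsv, read_manifest_tsv
from .preprocess import PairedDesign, PCAResult, beta_to_m, run_pca, select_variable_probes


class PairedMethylationModel:
    """Paired treated-vs-control methylation analysis of one or more groups.

    Parameters
    ----------
    beta : probes x samples beta-value DataFrame, already filtered/normalized.
    design : PairedDesign naming each group's treated and control sample.
    manifest : optional probe annotation table (chromosome, gene_region,
        island_relation) indexed by probe id; required for gene-level output.
    params : ParameterSet of thresholds; defaults match the procedure's
        canonical values (Q3 CV filter, |delta beta| > 0.2).
    """

    def __init__(
        self,
        beta: pd.DataFrame,
        design: PairedDesign,
        manifest: pd.DataFrame | None = None,
        params: ParameterSet | None = None,
    ) -> None:
        design.validate_against(beta)
        self.beta = beta
        self.design = design
        self.manifest = manifest
        self.params = params or ParameterSet()

    @classmethod
    def from_files(
        cls,
        beta_path,
        design_path,
        manifest_path=None,
        params: ParameterSet | None = None,
    ) -> "PairedMethylationModel":
        return cls(
            beta=read_beta_tsv(beta_path),
            design=PairedDesign.from_json(design_path),
            manifest=read_manifest_tsv(manifest_path) if manifest_path else None,
            params=params,
        )

    def fit(
        self, cv_method: str = "mad_median", inclusive_quantile: bool = True
    ) -> "PairedMethylationResults":
        calls = call_dmcpgs(
            self.beta,
            self.design,
            self.params,
            cv_method=cv_method,
            inclusive_quantile=inclusive_quantile,
        )
        dmgenes = island_tally = venn = common = None
        if self.manifest is not None:
            mapping = ann.map_dmcpgs_to_genes(calls.dmcpgs, self.manifest)
            dmgenes = mapping
            island_tally = ann.island_relation_summary(calls.dmcpgs, self.manifest)
            if len(self.design.groups) >= 2:
                venn = self._venn_all_groups(mapping.dmgenes)
                common = integ.common_genes(venn, self.params.min_groups_common)
        return PairedMethylationResults(
            model=self,
            calls=calls,
            gene_mapping=dmgenes,
            island_tally=island_tally,
            venn=venn,
            common=common,
        )

    def _venn_all_groups(self, dmgenes: pd.DataFrame):
        groups = self.design.group_names
        out = {}
        for (region_class, direction), sub in dmgenes.groupby(
            ["region_class", "direction"], sort=True
        ):
            per_group = {g: set(sub.loc[sub["group"] == g, "gene"]) for g in groups}
            out[(region_class, direction)] = integ.venn_counts(per_group)
        return out

    def pca(self, n_components: int | None = None) -> PCAResult:
        """Sample-relationship PCA on M-values of the variable probes."""
        m = beta_to_m(self.beta, self.params.m_epsilon)
        probes = select_variable_probes(m, self.params.var_ratio_threshold)
        if len(probes) < 2:  # degenerate screen; fall back to all probes
            probes = m.index
        return run_pca(m, probes, n_components=n_components)


@dataclass
class PairedMethylationResults:
    """Fitted per-group dmCpG calls and their gene-level projections."""

    model: PairedMethylationModel
    calls: DmCallResult
    gene_mapping: ann.GeneMappingResult | None = None
    island_tally: ann.IslandRegionTally | None = None
    venn: dict | None = None
    common: integ.CommonGenes | None = None

    @property
    def dmcpgs(self) -> pd.DataFrame:
        return self.calls.dmcpgs

    @property
    def dmgenes(self) -> pd.DataFrame | None:
        return None if self.gene_mapping is None else self.gene_mapping.dmgenes

    def integrate(
        self, degs: pd.DataFrame, alpha: float | None = None
    ) -> integ.IntegrationResult:
        """Cross the common dmGs with a differential-expression table."""
        if self.common is None:
            raise ValueError(
                "no common-gene set available: fit with a manifest and >= 2 groups"
            )
        return integ.cross_dmg_deg(
            self.common, degs, alpha=alpha or self.model.params.enrich_alpha
        )

    def enrich(
        self,
        collection: GeneSetCollection,
        universe: set[str] | None = None,
        alpha: float | None = None,
        min_size: int | None = None,
        max_size: int | None = None,
    ) -> EnrichmentResult:
        """ORA of the common genes; universe defaults to all manifest genes."""
        if self.common is None:
            raise ValueError("no common-gene set available for enrichment")
        if universe is None:
            if self.model.manifest is None:
                raise ValueError("pass a universe or fit with a manifest")
            universe = {
                gene
                for fieldval in self.model.manifest["gene_region"]
                for gene, _ in ann.parse_gene_region(fieldval)
            }
        return ora(
            self.common.genes(),
            universe,
            collection,
            alpha=alpha or self.model.params.enrich_alpha,
            min_size=min_size,
            max_size=max_size,
        )

    def summary(self) -> str:
        """Human-readable per-group call counts and intersection totals."""
        lines = ["Paired differential methylation (npCV / Q3 / |dB|) summary", ""]
        lines.append(
            f"{'group':<8}{'probes':>8}{'q3_cv':>10}{'retained':>10}"
            f"{'dmCpG':>8}{'hypo':>7}{'hyper':>7}"
        )
        for g, s in self.calls.summary.items():
            lines.append(
                f"{g:<8}{s.n_probes:>8}{s.q3_cutoff:>10.4f}{s.n_retained:>10}"
                f"{s.n_dmcpg:>8}{s.n_hypo:>7}{s.n_hyper:>7}"
            )
        if self.dmgenes is not None:
            lines.append("")
            for g in self.model.design.group_names:
                sub = self.dmgenes[self.dmgenes["group"] == g]
                lines.append(
                    f"group {g}: {sub['gene'].nunique()} dmGs "
                    f"({(sub['direction'] == 'hypo').sum()} hypo, "
                    f"{(sub['direction'] == 'hyper').sum()} hyper records)"
                )
        if self.common is not None:
            by_dir = self.common.distinct_by_direction()
            lines.append("")
            lines.append(
                f"common dmGs (>= {self.common.min_groups} groups): "
                f"{self.common.n_distinct} distinct "
                + ", ".join(f"{v} {k}" for k, v in by_dir.items())
            )
        return "\n".join(lines)
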
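"""Model / Results surface over the pleiotropy pipeline.

:class:`PleiotropyModel` holds the ingested data (association records, study
records, gene annotation, configuration); :meth:`PleiotropyModel.fit` runs
the full analysis for one set of settings — study and association filters,
positional (or author-reported) gene mapping with MHC exclusion, per-study
dedup, phenotype gene sets for the requested ancestry stratum, k-way overlap
enumeration, and both significance tests — and returns a
:class:`PleiotropyResults` carrying the estimates, diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import catalog_io, gene_mapping, network_viz, overlap, significance
from .config import AnalysisConfig, PHENOTYPES


class PleiotropyModel:
    """Cross-phenotype overlap analysis of a GWAS-catalog association table.

    Parameters
    ----------
    records, studies
        Output of :func:`pleioscan.catalog_io.read_catalog`.
    genes
        Gene models (:func:`pleioscan.gene_mapping.read_annotation`).
    config
        Analysis configuration; defaults apply when omitted.
    """

    def __init__(self, records, studies, genes, config: AnalysisConfig | None = None):
        self.config = config or AnalysisConfig()
        self.records = records
        self.studies = studies
        self.genes = gene_mapping.flag_mhc_genes(list(genes), self.config.mhc_region)
        self.index = gene_mapping.GenomeIndex(self.genes)
        self._phenotype_configs = [
            catalog_io.PhenotypeConfig(p, kws)
            for p, kws in self.config.phenotype_keywords.items()
        ]

    @classmethod
    def from_files(cls, catalog_path, annotation_path, config: AnalysisConfig | None = None):
        config = config or AnalysisConfig()
        records, studies = catalog_io.read_catalog(catalog_path, dialect=config.dialect)
        genes = gene_mapping.read_annotation(annotation_path)
        return cls(records, studies, genes, config)

    @classmethod
    def from_synthetic(cls, sim_config=None, config: AnalysisConfig | None = None):
        """Build a model directly from the synthetic-data generator."""
        import io

        from .synthetic_data import SimulationConfig, simulate_annotation, simulate_catalog

        sim_config = sim_config or SimulationConfig()
        genes, mhc_region = simulate_annotation(sim_config)
        catalog_df, truth = simulate_catalog(sim_config, genes)
        buf = io.StringIO()
        catalog_df.to_csv(buf, sep="\t", index=False)
        buf.seek(0)
        config = config or AnalysisConfig()
        config.mhc_region = mhc_region
        records, studies = catalog_io.read_catalog(buf, dialect=config.dialect)
        model = cls(records, studies, genes, config)
        model.ground_truth = truth
        return model

    def fit(
        self,
        stratum: str = "pooled",
        p_threshold: float | None = None,
        gene_mode: str = "positional",
        k_min: int = 2,
        replicates: int = significance.DEFAULT_REPLICATES,
        seed: int = 0,
        method: str = "closed_form",
        permutation: bool = True,
    ) -> "PleiotropyResults":
        """Run the pipeline and score all overlaps.

        ``p_threshold=None`` uses the config default (1e-5); pass 1e-7 for
        the stringent rerun.  ``permutation=False`` skips the weighted
        permutation null (the closed form is still computed).
        """
        cfg = self.config
        p_thr = cfg.p_threshold if p_threshold is None else p_threshold

        study_filter = catalog_io.filter_studies(self.studies, cfg.min_platform_snps)
        excluded_ids = study_filter.excluded_ids
        records = [r for r in self.records if r.study_id not in excluded_ids]
        assoc_filter = catalog_io.filter_associations(records, p_thr)

        normalized = catalog_io.normalize(
            assoc_filter.kept, self._phenotype_configs, cfg.ancestry_keywords
        )
        gene_rows = gene_mapping.map_catalog(
            normalized, self.index, cfg.mhc_region, mode=gene_mode
        )
        gene_rows = gene_mapping.dedup_per_study_trait(gene_rows)

        pool_size = cfg.pool_size
        if pool_size is None:
            pool_size = int(gene_rows["gene"].nunique()) if not gene_rows.empty else 0

        sets = overlap.build_phenotype_gene_sets(gene_rows, stratum)
        overlaps = overlap.enumerate_overlaps(sets, k_min=k_min, pool_size=pool_size)
        pool = significance.build_weighted_pool(gene_rows) if permutation else None
        scored = significance.score_all_overlaps(
            overlaps, pool, replicates=replicates, seed=seed, method=method
        )
        return PleiotropyResults(
            model=self,
            stratum=stratum,
            p_threshold=p_thr,
            gene_mode=gene_mode,
            seed=seed,
            pool_size=pool_size,
            gene_sets=sets,
            gene_table=gene_rows,
            normalized=normalized,
            overlaps=overlaps,
            significance=scored,
            study_filter=study_filter,
            n_assoc_excluded=assoc_filter.n_excluded_threshold,
            n_assoc_missing_p=assoc_filter.n_missing_p,
        )


@dataclass
class PleiotropyResults:
    """Fitted estimates and diagnostics for one analysis run."""

    model: PleiotropyModel
    stratum: str
    p_threshold: float
    gene_mode: str
    seed: int
    pool_size: int
    gene_sets: dict[str, overlap.PhenotypeGeneSet]
    gene_table: pd.DataFrame
    normalized: pd.DataFrame
    overlaps: list[overlap.OverlapResult]
    significance: list[significance.SignificanceResult]
    study_filter: catalog_io.StudyFilterResult
    n_assoc_excluded: int
    n_assoc_missing_p: int
    _genetic_graph: object = field(default=None, repr=False)

    @property
    def significance_table(self) -> pd.DataFrame:
        return significance.results_to_frame(self.significance)

    @property
    def overlap_table(self) -> pd.DataFrame:
        return overlap.overlaps_to_frame(self.overlaps)

    @property
    def counts_table(self) -> pd.DataFrame:
        return overlap.summarize_counts(self.normalized, self.gene_table)

    @property
    def pleiotropy_report(self) -> pd.DataFrame:
        return overlap.gene_pleiotropy_report(self.gene_sets)

    @property
    def n_pleiotropic_genes(self) -> int:
        """Genes shared by two or more phenotype sets in this stratum."""
        return len(self.pleiotropy_report)

    def genetic_graph(self, denominator: str = "multiplicity"):
        if self._genetic_graph is None:
            self._genetic_graph = network_viz.build_genetic_graph(
                self.gene_sets, denominator=denominator
            )
        return self._genetic_graph

    def replicated_edges(self, reference=None) -> network_viz.EdgeReplication:
        """Compare the genetic graph against an epidemiological reference.

        ``reference`` may be a networkx graph, an edge list, or None (config
        edges; complete 6-clique if the config declares none).
        """
        import networkx as nx

        if reference is None:
            reference = network_viz.reference_graph(self.model.config.reference_edges)
        elif not isinstance(reference, nx.Graph):
            reference = network_viz.reference_graph(list(reference))
        return network_viz.replicated_edges(self.genetic_graph(), reference)

    def plot_network(self, ax=None):
        return network_viz.plot_network(self.genetic_graph(), ax=ax)

    def summary(self) -> str:
        """Human-readable run summary: filters, per-phenotype list sizes,
        and the scored overlaps."""
        lines = [
            "Cross-phenotype pleiotropy analysis",
            "=" * 51,
            f"stratum: {self.stratum}   gene mode: {self.gene_mode}   "
            f"P threshold: {self.p_threshold:g}",
            f"studies kept: {len(self.study_filter.kept)}   "
            f"excluded: {len(self.study_filter.excluded)}",
            f"associations excluded at threshold: {self.n_assoc_excluded}   "
            f"missing p: {self.n_assoc_missing_p}",
            f"gene pool size N: {self.pool_size}",
            "",
            "Phenotype gene-list sizes:",
        ]
        for p in PHENOTYPES:
            if p in self.gene_sets:
                lines.append(f"  {p:<8} {self.gene_sets[p].size}")
        lines.append(f"  shared by 2+ phenotypes: {self.n_pleiotropic_genes}")
        lines.append("")
        if self.significance:
            df = self.significance_table[
                ["phenotypes", "k_observed", "shared_genes", "hypergeom_p", "permutation_p"]
            ].copy()
            df["hypergeom_p"] = df["hypergeom_p"].map(lambda v: f"{v:.3g}")
            df["permutation_p"] = df["permutation_p"].map(
                lambda v: "-" if v is None or pd.isna(v) else f"{v:.3g}"
            )
            lines.append("Overlaps (k = intersection size):")
            lines.append(df.to_string(index=False))
        else:
            lines.append("No overlapping gene sets detected.")
        return "\n".join(lines)
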
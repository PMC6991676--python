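"""End-to-end orchestration: DEGs -> DLs -> network -> modules -> enrichment.

``run_all`` executes the whole dynamic-signature workflow on one dataset
and returns a structured report mirroring the study's result tables:
dynamic-DEG counts at both FDR levels, DL counts before and after the
background-interaction mapping, the degree-ranked hub table, the
module-trait correlation matrix and any gene-set enrichments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from . import coexpr_modules as cm
from . import diffexpr, dyncoexpr, dynnet, enrichment
from .iolib import EdgeTable, ExpressionDataset, GeneSetCollection, RunConfig

logger = logging.getLogger("dynprognet")


@dataclass
class PipelineReport:
    config: RunConfig
    deg_table: pd.DataFrame
    n_dynamic_degs: int
    n_dynamic_degs_strict: int
    dl_table: pd.DataFrame
    n_dynamic_dls: int
    network: nx.Graph | None
    n_network_edges: int
    hub_table: pd.DataFrame | None
    scan: cm.SoftThresholdScan | None
    assignment: cm.ModuleAssignment | None
    enrichment_tables: dict[str, pd.DataFrame]

    def summary(self) -> dict:
        out = {
            "thresholds": self.config.to_dict(),
            "n_dynamic_degs": self.n_dynamic_degs,
            "n_dynamic_degs_strict": self.n_dynamic_degs_strict,
            "n_dynamic_dls": self.n_dynamic_dls,
            "n_network_edges": self.n_network_edges,
        }
        if self.network is not None:
            out["n_network_nodes"] = self.network.number_of_nodes()
        if self.scan is not None:
            out["chosen_beta"] = self.scan.chosen_beta
            out["beta_reached_target"] = self.scan.reached_target
        if self.assignment is not None:
            counts = self.assignment.module_of.value_counts()
            out["module_sizes"] = counts.to_dict()
        return out


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_all(dataset: ExpressionDataset,
            config: RunConfig | None = None,
            backgrounds: list[EdgeTable] | None = None,
            gene_sets: GeneSetCollection | None = None,
            probe_map: dict[str, str] | None = None,
            run_modules: bool = True) -> PipelineReport:
    """Run the full workflow on one dataset.

    The dataset must carry exactly three ordered stages for the dynamic
    analyses.  ``backgrounds`` supplies the interaction tables to merge
    (the DL mapping is skipped when absent); ``gene_sets`` triggers
    over-representation of the dynamic DEGs; ``probe_map`` collapses
    probe rows to genes first.
    """
    cfg = config or RunConfig()
    logger.info("run_all: thresholds %s", cfg.to_dict())

    d = dataset
    if probe_map is not None:
        d = _stage("collapse")(diffexpr.collapse_probes_mean)(d, probe_map)
    z = _stage("zscore")(diffexpr.zscore_normalize)(d)
    test_input = d if cfg.ttest_on_raw else z

    # --- differential expression over both transitions
    (e1, l1), (e2, l2) = d.transitions()[:2]
    s1 = _stage("deg")(diffexpr.ttest_transition)(test_input, e1, l1, cfg.welch)
    s2 = _stage("deg")(diffexpr.ttest_transition)(test_input, e2, l2, cfg.welch)
    dyn = diffexpr.dynamic_degs(s1, s2, cfg.fdr_deg)
    dyn_strict = diffexpr.dynamic_degs(s1, s2, cfg.fdr_deg_strict)
    deg_table = diffexpr.deg_result_table(s1, s2, dyn)

    # --- differentially co-expressed links
    dl_table = _stage("dls")(dyncoexpr.dynamic_link_table)(
        z, low=cfg.dpcc_low, high=cfg.dpcc_high,
        require_sign_flip=cfg.require_sign_flip, block_size=cfg.block_size)
    n_dyn_dls = int(dl_table["is_dynamic_dl"].sum())

    # --- dynamic network on the merged background
    network = None
    hub_table = None
    n_edges = 0
    if backgrounds:
        merged = _stage("network")(dynnet.merge_backgrounds)(backgrounds)
        node_attrs = pd.DataFrame(index=pd.Index(d.genes, name="gene"))
        for stage in d.stage_order:
            node_attrs[f"mean_{stage}"] = d.stage_matrix(stage).mean(axis=1)
        node_attrs["dynamic_deg"] = node_attrs.index.isin(dyn.genes)
        node_attrs["strict_deg"] = node_attrs.index.isin(dyn_strict.genes)
        network = _stage("network")(dynnet.map_dls_to_ppi)(
            dl_table, merged, mode=cfg.map_mode, node_attrs=node_attrs)
        dynnet.annotate_shared_neighbours(network, merged)
        n_edges = network.number_of_edges()
        hub_table = dynnet.hub_ranking(network)

    # --- co-expression modules and trait correlations
    scan = None
    assignment = None
    if run_modules and len(d.genes) >= 20 and len(d.samples) >= 4:
        scan = _stage("modules")(cm.soft_threshold_scan)(
            z, powers=list(cfg.powers), target_r2=cfg.target_r2)
        assignment, adj = _stage("modules")(cm.detect_modules_from_expression)(
            z, beta=scan.chosen_beta, min_module_size=cfg.min_module_size,
            cut_height=cfg.cut_height, merge_height=cfg.merge_height)
        cm.intramodular_connectivity(adj, assignment)
        if d.traits is not None and assignment.eigengenes is not None \
                and not assignment.eigengenes.empty:
            r, p = cm.module_trait_correlation(assignment.eigengenes, d.traits)
            assignment.module_trait_r, assignment.module_trait_p = r, p
            cm.gene_significance_and_mm(z, d.traits, assignment)

    # --- enrichment of the dynamic DEGs
    tables: dict[str, pd.DataFrame] = {}
    if gene_sets is not None and dyn.genes:
        tables["dynamic_degs"] = _stage("enrich")(enrichment.hypergeom_enrich)(
            set(dyn.genes), gene_sets, set(d.genes), alpha=cfg.fdr_deg)

    report = PipelineReport(
        config=cfg, deg_table=deg_table,
        n_dynamic_degs=len(dyn.genes),
        n_dynamic_degs_strict=len(dyn_strict.genes),
        dl_table=dl_table, n_dynamic_dls=n_dyn_dls,
        network=network, n_network_edges=n_edges, hub_table=hub_table,
        scan=scan, assignment=assignment, enrichment_tables=tables)
    logger.info("run_all: %s", report.summary())
    return report
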
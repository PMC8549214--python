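"""End-to-end orchestration of the multi-omics + network-pharmacology run.

:func:`run_all` wires the stages in dependency order — synthetic data (or a
directory of previously written inputs), proteomics QC and DP calling,
metabolomics DM calling, formula target aggregation and signatures, disease
and drug overlap, PPI label propagation, integrated metabolite-gene
networks, enrichment with term clustering, biomarker panels — and returns a
machine-readable report dictionary whose JSON serialization is
byte-identical for identical configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from zhengomics import diffmet, diffprot, enrich, netgraph, netpharm, panelroc
from zhengomics.syndata import (
    SynConfig,
    gen_knowledgebase,
    gen_metabolomics,
    gen_proteomics,
)
from zhengomics.tables import OmicsTable

REPORT_SCHEMA_VERSION = 1

SYNDROMES = ("CCQS", "QSBS")

#: the nine report sections every complete run must contain
REPORT_SECTIONS = (
    "differential_omics",
    "formula_counts",
    "signature_partitions",
    "disease_drug_overlap",
    "enrichment",
    "clusters",
    "integrated_networks",
    "panel_auc",
    "cross_view_consistency",
)


@dataclass
class RunConfig:
    """Thresholds and inputs of one pipeline run."""

    syn: SynConfig = field(default_factory=SynConfig)
    fc_thresh: float = 1.1
    p_thresh: float = 0.05
    vip_thresh: float = 1.0
    fdr_thresh: float = 0.05
    ob_thresh: float = 30.0
    dl_thresh: float = 0.18
    jig_thresh: float = 0.2
    jiv_thresh: float = 0.05
    alpha: float = 0.5
    topk: int = 10
    stringency: str = "high"
    quantified_presence: float = 0.7
    panel_size: int = 4


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (set, frozenset)):
        return sorted(str(x) for x in obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def quantified_subset(prot: OmicsTable, min_presence: float) -> OmicsTable:
    """Quantifiable features: observed in >= ``min_presence`` of cohort samples."""
    cohort = prot.subset_groups(list(SYNDROMES) + ["HC"])
    presence = cohort.values.notna().mean(axis=1)
    keep = presence[presence >= min_presence].index
    return OmicsTable(prot.values.loc[keep], prot.groups, prot.feature_meta)


def run_all(config: RunConfig) -> dict:
    """Execute every stage on a self-contained synthetic run."""
    cfg = config.syn
    seed = cfg.seed

    prot, _ = gen_proteomics(cfg)
    unt, tgt, _ = gen_metabolomics(cfg)
    kb, _ = gen_knowledgebase(cfg)

    # ---- proteomics QC + DPs ------------------------------------------------
    quant = quantified_subset(prot, config.quantified_presence)
    cv = diffprot.qc_cv(quant)
    imputed = diffprot.impute_missing(quant)
    corr = diffprot.qc_correlation(imputed.subset_groups(list(SYNDROMES) + ["HC"]))
    off_diag = corr.to_numpy()[~np.eye(len(corr), dtype=bool)]

    dp_tables = {
        syn: diffprot.diff_proteins(imputed, syn, "HC", config.fc_thresh, config.p_thresh)
        for syn in SYNDROMES
    }
    dp_sets = {
        syn: set(t.loc[t["significant"], "protein"]) for syn, t in dp_tables.items()
    }
    dp_common, dp_ccqs_only, dp_qsbs_only = diffprot.venn_sets(
        dp_sets["CCQS"], dp_sets["QSBS"]
    )

    # ---- metabolomics DMs ---------------------------------------------------
    dm_tables, dm_models = {}, {}
    for mode, table in (("untargeted", unt), ("targeted", tgt)):
        for syn in SYNDROMES:
            dm, model = diffmet.differential_metabolites(table, syn, "HC", mode, seed=seed)
            dm_tables[(mode, syn)] = dm
            dm_models[(mode, syn)] = model
    dm_sets = {
        syn: set(dm_tables[("untargeted", syn)].query("significant")["metabolite"])
        for syn in SYNDROMES
    }
    dm_common, dm_ccqs_only, dm_qsbs_only = diffprot.venn_sets(
        dm_sets["CCQS"], dm_sets["QSBS"]
    )
    cat_props = {
        syn: diffmet.category_proportions(dm_tables[("untargeted", syn)]).to_dict()
        for syn in SYNDROMES
    }

    # ---- network pharmacology ----------------------------------------------
    active = netpharm.filter_active(kb.compounds, config.ob_thresh, config.dl_thresh)
    ft = {f.code: netpharm.formula_targets(f, active) for f in kb.formulae}
    sig = {
        "CCQS": netpharm.signature_targets(ft["F1-1"].targets, ft["F1-2"].targets,
                                           ft["F1-3"].targets),
        "QSBS": netpharm.signature_targets(ft["F2-1"].targets, ft["F2-2"].targets,
                                           ft["F2-3"].targets),
    }
    sig_common, sig_f1_only, sig_f2_only = netpharm.specific_signatures(
        sig["CCQS"], sig["QSBS"]
    )
    partitions = {"common": sig_common, "F1_only": sig_f1_only, "F2_only": sig_f2_only}
    disease_table = netpharm.disease_similarity(
        kb.chd, kb.diseases, config.jig_thresh, config.jiv_thresh
    )
    drug_counts, drug_net = netpharm.map_drug_overlap(partitions, kb.drugs)

    # ---- PPI label propagation ---------------------------------------------
    ppi_sections = {}
    for syn in SYNDROMES:
        seeds = dp_sets[syn] & set(kb.ppi.nodes)
        prop = netgraph.label_propagate(kb.ppi, seeds, alpha=config.alpha)
        nodes, subnet = netgraph.expand_top_k(kb.ppi, prop, k=config.topk)
        ppi_sections[syn] = {
            "n_seeds": len(seeds),
            "added_genes": sorted(set(nodes) - seeds),
            "n_edges": subnet.number_of_edges(),
        }

    # ---- integrated metabolite-gene networks -------------------------------
    integrated = {}
    integrated_nets = {}
    for syn in SYNDROMES:
        sub = netgraph.extract_metabolite_gene_network(
            kb.metgene, dm_sets[syn], dp_sets[syn],
            signature_targets=sig[syn],
        )
        integrated_nets[syn] = sub
        origins = [d["origin"] for _, d in sub.nodes(data=True)]
        integrated[syn] = {
            "n_nodes": sub.number_of_nodes(),
            "n_edges": sub.number_of_edges(),
            "n_metabolites": origins.count("DM"),
            "n_genes": origins.count("DP") + origins.count("signature"),
            "n_bridges": origins.count("bridge"),
        }

    # ---- enrichment + consistency ------------------------------------------
    gene_universe = set().union(*kb.pathways_genes.values())
    met_universe = set().union(*kb.pathways_mets.values())
    joint_universe = gene_universe | met_universe
    enrichment = {}
    hits: dict[str, dict[str, set]] = {}
    for syn in SYNDROMES:
        views = {}
        views["proteomics"] = (
            enrich.ora(dp_sets[syn], kb.pathways_genes, gene_universe)
            if dp_sets[syn] & gene_universe else None
        )
        views["metabolomics"] = (
            enrich.ora(dm_sets[syn], kb.pathways_mets, met_universe)
            if dm_sets[syn] & met_universe else None
        )
        genes_q = dp_sets[syn] | (sig[syn] & gene_universe)
        mets_q = dm_sets[syn]
        views["integrated"] = (
            enrich.joint_ora(genes_q, mets_q, kb.pathways_joint, joint_universe)
            if (genes_q | mets_q) & joint_universe else None
        )
        enrichment[syn] = {
            view: (t.head(10).to_dict(orient="records") if t is not None else [])
            for view, t in views.items()
        }
        hits[syn] = {
            view: (set(t.loc[t["p"] < config.p_thresh, "term"]) if t is not None else set())
            for view, t in views.items()
        }
    consistency = enrich.cross_view_consistency(hits)

    # ---- disease-term clustering (kappa) -----------------------------------
    disease_sets = {d.disease_id: set(d.genes) for d in kb.diseases}
    disease_universe = set().union(*disease_sets.values())
    clusters = {}
    for syn in SYNDROMES:
        query = dp_sets[syn] & disease_universe
        if len(query) < 2:
            clusters[syn] = []
            continue
        rows = enrich.ora(query, disease_sets, disease_universe)
        kap = enrich.kappa_matrix(query, disease_sets)
        cl = enrich.cluster_terms(rows, kap, stringency=config.stringency)
        clusters[syn] = [
            {"rank": c.rank, "score": c.score, "members": c.members} for c in cl[:5]
        ]

    # ---- biomarker panels ---------------------------------------------------
    specific_dp = {"CCQS": dp_ccqs_only, "QSBS": dp_qsbs_only}
    panel_auc = {}
    log2 = np.log2(imputed.values)
    for syn in SYNDROMES:
        ordered = dp_tables[syn].loc[
            dp_tables[syn]["protein"].isin(specific_dp[syn]), "protein"
        ].tolist()
        markers = ordered[: config.panel_size]
        if len(markers) < 2:
            panel_auc[syn] = {"markers": markers, "auc_own": None, "auc_cross": None}
            continue
        other = "QSBS" if syn == "CCQS" else "CCQS"
        own_samples = imputed.samples_in_group(syn) + imputed.samples_in_group("HC")
        other_samples = imputed.samples_in_group(other) + imputed.samples_in_group("HC")
        y_own = np.array([imputed.groups[s] == syn for s in own_samples], dtype=int)
        y_other = np.array([imputed.groups[s] == other for s in other_samples], dtype=int)
        panel = panelroc.fit_panel(log2[own_samples], y_own, markers)
        roc_own = panelroc.cross_apply(panel, log2[own_samples], y_own)
        roc_cross = panelroc.cross_apply(panel, log2[other_samples], y_other)
        panel_auc[syn] = {
            "markers": markers,
            "auc_own": roc_own.auc,
            "auc_cross": roc_cross.auc,
        }

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "parameters": {**asdict(cfg), **{k: v for k, v in asdict(config).items() if k != "syn"}},
        "qc": {
            "n_quantified": int(quant.values.shape[0]),
            "cv_below_0.10": diffprot.fraction_below(cv, 0.10),
            "min_sample_correlation": float(np.nanmin(off_diag)),
        },
        "differential_omics": {
            "dp_counts": {syn: len(dp_sets[syn]) for syn in SYNDROMES},
            "dp_venn": {"common": dp_common, "ccqs_only": dp_ccqs_only,
                        "qsbs_only": dp_qsbs_only},
            "dm_counts": {syn: len(dm_sets[syn]) for syn in SYNDROMES},
            "dm_venn": {"common": dm_common, "ccqs_only": dm_ccqs_only,
                        "qsbs_only": dm_qsbs_only},
            "dm_category_proportions": cat_props,
            "q2": {f"{mode}_{syn}": dm_models[(mode, syn)].q2
                   for mode in ("untargeted", "targeted") for syn in SYNDROMES},
        },
        "formula_counts": {
            code: {"n_herbs": len(next(f for f in kb.formulae if f.code == code).herbs),
                   "n_active": t.n_active,
                   "n_active_with_targets": t.n_active_with_targets,
                   "n_targets": t.n_targets}
            for code, t in ft.items()
        },
        "signature_partitions": {
            "n_sig_ccqs": len(sig["CCQS"]),
            "n_sig_qsbs": len(sig["QSBS"]),
            "common": sig_common,
            "f1_only": sig_f1_only,
            "f2_only": sig_f2_only,
        },
        "disease_drug_overlap": {
            "n_related_diseases": int(disease_table["related"].sum()),
            "diseases": disease_table[disease_table["related"]]["disease"].tolist(),
            "drug_target_counts": drug_counts.to_dict(orient="index"),
            "n_drug_edges": drug_net.number_of_edges(),
        },
        "enrichment": enrichment,
        "clusters": clusters,
        "integrated_networks": integrated,
        "panel_auc": panel_auc,
        "cross_view_consistency": consistency.to_dict(orient="records"),
        "ppi_networks": ppi_sections,
    }
    return _jsonable(report)


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)


def run_and_write(config: RunConfig, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = run_all(config)
    (outdir / "report.json").write_text(report_to_json(report))
    return report
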
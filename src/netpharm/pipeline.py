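"""End-to-end orchestration: annotate -> predict -> network -> enrich -> qpcr.

Every stage reads and writes plain-text artifacts so any step can be re-run
and diffed; each output file and the final JSON report carry the hash of the
configuration that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from . import enrich as enrich_mod
from . import masslib, netfilter, qpcr, targetmap

log = logging.getLogger("netpharm")

__all__ = ["RunConfig", "run_all", "config_hash"]


@dataclass
class RunConfig:
    out_dir: str = "netpharm_out"
    seed: int = 0
    # inputs (any stage with a missing input is skipped unless toggled on)
    peaks_path: Optional[str] = None
    compound_library_path: Optional[str] = None
    query_fingerprints_path: Optional[str] = None
    drug_library_path: Optional[str] = None
    edges_path: Optional[str] = None
    roles_path: Optional[str] = None
    disease_genes_path: Optional[str] = None
    gmt_path: Optional[str] = None
    enrich_query_path: Optional[str] = None
    ct_table_path: Optional[str] = None
    # parameters
    ppm_tol: float = 10.0
    similarity_threshold: float = 0.8
    min_confidence: float = 0.4
    alpha: float = 0.05
    ref_gene: str = "ACTB"
    control_group: str = "control"
    # stage toggles
    do_annotate: bool = True
    do_predict: bool = True
    do_network: bool = True
    do_enrich: bool = True
    do_qpcr: bool = True

    def validate(self) -> None:
        if self.ppm_tol <= 0:
            raise ValueError("ppm_tol must be positive")
        if not 0 <= self.similarity_threshold <= 1:
            raise ValueError("similarity_threshold must lie in [0, 1]")
        if not 0 <= self.min_confidence <= 1:
            raise ValueError("min_confidence must lie in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _read_gene_list(path) -> set[str]:
    return {
        ln.strip().upper()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    }


def _read_roles(path) -> dict[str, str]:
    roles = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith("#") or ln.startswith("node\t"):
            continue
        node, role = ln.split("\t")
        roles[node] = role
    return roles


def run_all(cfg: RunConfig) -> dict:
    """Execute every enabled stage; returns the machine-readable report."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    stamp = f"netpharm {__version__} config_hash={chash} seed={cfg.seed}"
    log.info("run start: %s", stamp)

    report: dict = {
        "version": __version__,
        "config_hash": chash,
        "seed": cfg.seed,
        "counts": {},
        "stages": [],
    }
    counts = report["counts"]
    predictions: list[targetmap.TargetPrediction] = []
    candidate_targets: set[str] = set()

    if cfg.do_annotate:
        if not (cfg.peaks_path and cfg.compound_library_path):
            raise ValueError("annotate stage enabled but peaks/library paths missing")
        try:
            peaks = masslib.read_peak_table(cfg.peaks_path)
            library = masslib.read_compound_library(cfg.compound_library_path)
            annotations = masslib.annotate_peaks(peaks, library, tol=cfg.ppm_tol)
        except Exception as exc:
            raise RuntimeError(f"stage 'annotate' failed: {exc}") from exc
        masslib.write_annotations(annotations, out / "annotations.tsv", stamp)
        counts["peaks"] = len(peaks)
        counts["annotations"] = len(annotations)
        counts["annotated_compounds"] = len({a.compound_id for a in annotations})
        report["stages"].append("annotate")
        log.info("annotate: %d peaks -> %d annotations", len(peaks), len(annotations))

    if cfg.do_predict:
        if not (cfg.query_fingerprints_path and cfg.drug_library_path):
            raise ValueError("predict stage enabled but fingerprint/drug paths missing")
        try:
            queries = targetmap.read_fingerprints(cfg.query_fingerprints_path)
            drugs = targetmap.read_drug_library(cfg.drug_library_path)
            for q in queries:
                predictions.extend(
                    targetmap.predict_targets(q, drugs, cfg.similarity_threshold)
                )
        except Exception as exc:
            raise RuntimeError(f"stage 'predict' failed: {exc}") from exc
        targetmap.write_predictions(predictions, out / "predictions.tsv", stamp)
        union = targetmap.aggregate_targets(predictions)
        counts["queries"] = len(queries)
        counts["predicted_targets"] = len(union)
        report["stages"].append("predict")
        log.info("predict: %d queries -> %d targets", len(queries), len(union))

    if cfg.do_network:
        if not cfg.edges_path:
            raise ValueError("network stage enabled but edges path missing")
        try:
            edges = netfilter.read_edge_list(cfg.edges_path)
            if cfg.roles_path:
                roles = _read_roles(cfg.roles_path)
                targets = {n for n, r in roles.items() if r in ("putative_target", "both")}
                disease = {n for n, r in roles.items() if r in ("disease_gene", "both")}
            else:
                targets = set(targetmap.aggregate_targets(predictions))
                disease = (
                    _read_gene_list(cfg.disease_genes_path)
                    if cfg.disease_genes_path
                    else set()
                )
            net = netfilter.build_network(targets, disease, edges, cfg.min_confidence)
            records = netfilter.centralities(net)
            hubs = netfilter.select_hubs(records)
            major = netfilter.refine_major_hubs(net, hubs)
            selection = netfilter.classify_candidates(major, net, hubs)
        except Exception as exc:
            raise RuntimeError(f"stage 'network' failed: {exc}") from exc
        candidate_targets = set(selection.candidate_targets)
        netfilter.write_sif(net, out / "network.sif")
        netfilter.write_node_attributes(
            net, records, hubs, major, out / "node_attributes.tsv", stamp
        )
        counts["nodes"] = len(net.nodes)
        counts["edges"] = net.n_edges
        counts["hubs"] = len(hubs)
        counts["major_hubs"] = len(major)
        counts["candidate_targets"] = len(candidate_targets)
        counts["major_disease_genes"] = len(selection.disease_genes)
        report["stages"].append("network")
        log.info(
            "network: %d nodes / %d edges -> %d hubs -> %d major hubs",
            len(net.nodes), net.n_edges, len(hubs), len(major),
        )

    significant_sets: list[enrich_mod.EnrichmentResult] = []
    if cfg.do_enrich:
        if not cfg.gmt_path:
            raise ValueError("enrich stage enabled but GMT path missing")
        try:
            coll = enrich_mod.read_gmt(cfg.gmt_path)
            if cfg.enrich_query_path:
                query = _read_gene_list(cfg.enrich_query_path)
            else:
                query = candidate_targets
            results = enrich_mod.run_enrichment(query, coll, cfg.alpha)
        except Exception as exc:
            raise RuntimeError(f"stage 'enrich' failed: {exc}") from exc
        enrich_mod.write_enrichment(results, out / "enrichment.tsv", stamp)
        significant_sets = [r for r in results if r.significant]
        counts["gene_sets"] = len(results)
        counts["significant_pathways"] = len(significant_sets)
        report["stages"].append("enrich")
        log.info("enrich: %d sets, %d significant", len(results), len(significant_sets))

    if cfg.do_qpcr and cfg.ct_table_path:
        try:
            cts = qpcr.read_ct_table(cfg.ct_table_path)
            expressions = qpcr.relative_expression(cts, cfg.ref_gene, cfg.control_group)
        except Exception as exc:
            raise RuntimeError(f"stage 'qpcr' failed: {exc}") from exc
        qpcr.write_expression(expressions, out / "expression.csv", stamp)
        summary = qpcr.group_summary(expressions)
        summary.to_csv(out / "expression_summary.csv", index=False)
        counts["qpcr_genes"] = summary["gene"].nunique()
        report["stages"].append("qpcr")
        log.info("qpcr: %d fold-change rows", len(expressions))

    # compound -> target -> pathway provenance chains
    if predictions and significant_sets:
        coll = enrich_mod.read_gmt(cfg.gmt_path)
        members = {s.name: s.genes for s in coll.sets}
        chains = []
        for p in predictions:
            for r in significant_sets:
                if p.gene in members[r.name]:
                    chains.append(
                        {"compound": p.compound_id, "target": p.gene, "pathway": r.name}
                    )
        report["provenance_chains"] = chains

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True))
    log.info("run complete: %s", report_path)
    return report
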
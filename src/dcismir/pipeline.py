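"""End-to-end orchestration: simulate (or load) → miRNA DE → mRNA DE →
pair integration → locus co-expression → enrichment, with a run manifest and,
on synthetic runs, recovery metrics against the planted truth.

The reports mirror the two table shapes a replication attempt would diff:
a per-miRNA table of fold / p / tier for the three comparisons, and a pair
table of (miRNA, miRNA fold, probe, gene, gene fold, r, p, class).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from .config import PipelineConfig
from .containers import GROUP_LESION, GROUP_NORMAL
from .enrich import ease_enrichment
from .integrate import IntegrationResult, run_integration
from .loci import cluster_coexpression, cluster_loci
from .microarray import GeneDEResult, run_mrna_de
from .qpcr import MirnaDEResult, run_mirna_de
from .simulate import SimulationDesign, simulate_bundle

logger = logging.getLogger("dcismir")

__all__ = ["RunManifest", "PipelineRun", "run_all", "recovery_metrics"]


@dataclass
class RunManifest:
    config: dict
    seed: Optional[int]
    counts: Dict[str, int] = field(default_factory=dict)
    outputs: Dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        c = self.counts
        if c.get("pairs_retained", 0) > c.get("pairs_candidate", 0):
            raise ValueError("manifest inconsistent: retained pairs exceed candidates")
        if c.get("mirna_significant", 0) > c.get("mirna_tested", 0):
            raise ValueError("manifest inconsistent: significant miRNA exceed tested")
        if c.get("genes_selected_probes", 0) > c.get("probes_tested", 0):
            raise ValueError("manifest inconsistent: selected probes exceed tested")


@dataclass
class PipelineRun:
    manifest: RunManifest
    mirna_de: MirnaDEResult
    gene_de: GeneDEResult
    integration: IntegrationResult
    clusters: list
    coexpression: dict
    enrichment: pd.DataFrame
    recovery: Optional[dict] = None


def recovery_metrics(truth: dict, mirna_de: MirnaDEResult,
                     gene_de: GeneDEResult, integration: IntegrationResult,
                     comparison: str = "DCIS-HN") -> dict:
    """Sensitivity/specificity of each stage against the planted truth."""
    true_mirna = set(truth.get("mirna_effects", {}))
    called_mirna = set(mirna_de.significant_in(comparison))
    tested_mirna = set(mirna_de.table.index)
    coupled = truth.get("coupled_pairs", [])
    true_probes = set(truth.get("gene_effects", {})) | {p for _m, p, _s in coupled}
    called_probes = set(gene_de.selected_probes)
    tested_probes = set(gene_de.table.index)
    true_pairs = {(m, p) for m, p, _s in coupled}
    called_pairs = set(zip(integration.pairs["mirna_id"],
                           integration.pairs["probe_id"]))

    def _sens(truth_set, called):
        return len(truth_set & called) / len(truth_set) if truth_set else float("nan")

    def _fpr(truth_set, called, tested):
        null = tested - truth_set
        return len(called - truth_set) / len(null) if null else float("nan")

    tp = len(true_pairs & called_pairs)
    precision = tp / len(called_pairs) if called_pairs else float("nan")
    recall = tp / len(true_pairs) if true_pairs else float("nan")
    f1 = (2 * precision * recall / (precision + recall)
          if called_pairs and true_pairs and (precision + recall) > 0 else 0.0)
    return {
        "mirna": {"sensitivity": _sens(true_mirna, called_mirna),
                  "false_positive_rate": _fpr(true_mirna, called_mirna, tested_mirna),
                  "n_called": len(called_mirna)},
        "genes": {"sensitivity": _sens(true_probes & tested_probes, called_probes),
                  "false_selection_rate": _fpr(true_probes, called_probes, tested_probes),
                  "n_called": len(called_probes)},
        "pairs": {"precision": precision, "recall": recall, "f1": f1,
                  "n_called": len(called_pairs), "n_true": len(true_pairs)},
    }


def load_bundle(ct_path, annotation_path, expr_path, probe_map_path,
                prediction_paths, bed_path, gmt_path,
                presence_path=None, programs=None,
                ct_max: float = 40.0) -> dict:
    """Assemble a pipeline input bundle from files (no planted truth)."""
    from . import io as dio

    annotation = dio.read_annotation(annotation_path)
    return {
        "ct": dio.read_ct_table(ct_path, annotation, ct_max=ct_max),
        "expr": dio.read_expression_matrix(expr_path, probe_map_path,
                                           annotation,
                                           presence_path=presence_path),
        "predictions": dio.read_prediction_tables(list(prediction_paths),
                                                  programs=programs),
        "loci": dio.read_bed_loci(bed_path),
        "gene_sets": dio.read_gmt(gmt_path),
        "truth": None,
    }


def run_all(cfg: PipelineConfig, design: Optional[SimulationDesign] = None,
            bundle: Optional[dict] = None, outdir=None,
            comparison: str = "DCIS-HN") -> PipelineRun:
    """Run every stage on a simulated or pre-loaded input bundle.

    ``bundle`` needs keys ct, expr, predictions, loci, gene_sets and
    optionally truth (as produced by :func:`dcismir.simulate.simulate_bundle`).
    Any stage failure aborts with the stage name; outputs written so far are
    left in place.
    """
    if (design is None) == (bundle is None):
        raise ValueError("provide exactly one of design or bundle")
    if design is not None:
        bundle = simulate_bundle(design)

    stage = "mirna_de"
    try:
        mirna_de = run_mirna_de(bundle["ct"], cfg)
        stage = "mrna_de"
        gene_de = run_mrna_de(bundle["expr"], cfg)
        stage = "integration"
        integration = run_integration(bundle["predictions"], mirna_de, gene_de,
                                      bundle["expr"], cfg, comparison)
        stage = "locus_coexpression"
        clusters, cluster_report = cluster_loci(bundle["loci"], cfg.cluster_gap_bp)
        coexpression = cluster_coexpression(clusters, mirna_de.normalized,
                                            loci=bundle["loci"])
        stage = "enrichment"
        study = sorted(set(integration.pairs["gene_symbol"].dropna()))
        background = sorted(set(gene_de.table["gene_symbol"].dropna()))
        enrichment = ease_enrichment(study, background, bundle["gene_sets"])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    recovery = None
    if bundle.get("truth"):
        recovery = recovery_metrics(bundle["truth"], mirna_de, gene_de,
                                    integration, comparison)

    manifest = RunManifest(
        config=cfg.to_dict(),
        seed=design.rng_seed if design is not None else None,
        counts={
            "mirna_input": len(bundle["ct"].values),
            "mirna_tested": len(mirna_de.table),
            "mirna_significant": len(mirna_de.significant),
            "probes_input": len(bundle["expr"].values),
            "probes_tested": len(gene_de.table),
            "probes_screened": int(gene_de.table["screened"].sum()),
            "genes_selected_probes": int(gene_de.table["selected"].sum()),
            "pairs_candidate": len(integration.candidate_pairs),
            "pairs_retained": len(integration.pairs),
            "pairs_inverse": integration.summary["inverse"]["pairs"],
            "pairs_coordinate": integration.summary["coordinate"]["pairs"],
            "pairs_undefined": integration.summary["undefined"]["pairs"],
            "locus_clusters": cluster_report["n_clusters"],
            "clustered_mirna": cluster_report["n_clustered_mirna"],
        })
    manifest.validate()
    run = PipelineRun(manifest=manifest, mirna_de=mirna_de, gene_de=gene_de,
                      integration=integration, clusters=clusters,
                      coexpression=coexpression, enrichment=enrichment,
                      recovery=recovery)
    if outdir is not None:
        write_reports(run, outdir)
    return run


def write_reports(run: PipelineRun, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def _path(name: str) -> Path:
        # names kept relative to the run directory so a rerun elsewhere
        # produces byte-identical reports
        run.manifest.outputs[name] = name
        return outdir / name

    run.mirna_de.table.rename_axis("mirna_id").reset_index().to_csv(
        _path("mirna_de.tsv"), sep="\t", index=False, float_format="%.6g")
    run.mirna_de.filter_report.rename_axis("mirna_id").reset_index().to_csv(
        _path("filter_report.tsv"), sep="\t", index=False)
    run.gene_de.table.rename_axis("probe_id").reset_index().to_csv(
        _path("mrna_de.tsv"), sep="\t", index=False, float_format="%.6g")
    run.integration.pairs.to_csv(_path("pairs.tsv"), sep="\t", index=False,
                                 float_format="%.6g")
    with open(_path("pair_summary.json"), "w") as fh:
        json.dump(run.integration.summary, fh, indent=2)
    cluster_rows = [{"chromosome": c.chromosome, "members": ",".join(c.members),
                     "span_bp": c.span,
                     "gaps_bp": ",".join(map(str, c.member_gaps))}
                    for c in run.clusters]
    pd.DataFrame(cluster_rows, columns=["chromosome", "members", "span_bp",
                                        "gaps_bp"]).to_csv(
        _path("clusters.tsv"), sep="\t", index=False)
    with open(_path("coexpression_summary.json"), "w") as fh:
        json.dump(run.coexpression, fh, indent=2)
    run.enrichment.to_csv(_path("enrichment.tsv"), sep="\t", index=False,
                          float_format="%.6g")
    if run.recovery is not None:
        with open(_path("recovery.json"), "w") as fh:
            json.dump(run.recovery, fh, indent=2)
    with open(_path("manifest.json"), "w") as fh:
        json.dump(dataclasses.asdict(run.manifest), fh, indent=2)
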
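"""End-to-end orchestration: QC -> DCE -> clustering/classification ->
correlation networks -> DCC -> reversed DCCs, with a reproducible bundle of
TSV/SIF/GraphML/JSON outputs.

All randomness flows from a single top-level seed through named substreams
(one per stage), so a stage re-run standalone with its substream seed
reproduces its part of the bundle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import (classify_groups, cluster_elements, linkage_to_newick,
                         profile_matrix, zscore_rows)
from .dataset import IonomeDataset, read_ionome_table, write_ionome_table
from .dce import dce_scan, dce_summary
from .io import write_graphml, write_sif, write_tsv
from .network import (DEFAULT_TAU_DCC, DEFAULT_TAU_SCC, dcc_scan,
                      group_specific_edges, overlap_and_reversed_dccs,
                      scc_matrix, scc_tables, simulate_dcc_threshold,
                      simulate_scc_threshold)
from .synthetic import default_config, generate_dataset

logger = logging.getLogger("ionnet")

STAGES = ("synthetic", "thresholds", "classify")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the master seed."""
    child = np.random.SeedSequence(seed, spawn_key=(STAGES.index(stage),))
    return int(child.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    """Settings for one full analysis run."""

    input_path: str | None = None       # None -> generate the default synthetic study
    reference_group: str = "WT"
    disease_group: str = "AD"
    treatment_group: str = "Se"
    alpha: float = 0.05
    tau_scc: float | None = None        # None -> simulate; number -> override
    tau_dcc: float | None = None
    inner_reps: int = 1000
    outer_reps: int = 200
    classification_labels: tuple[str, str] = ("Se", "AD")
    cluster_k: int = 4
    seed: int = 0
    output_dir: str = "ionnet_out"

    def validate(self) -> None:
        if self.tau_scc is not None and not 0 < self.tau_scc <= 1:
            raise ValueError("tau_scc override must be in (0, 1]")
        if self.tau_dcc is not None and not 0 < self.tau_dcc <= 2:
            raise ValueError("tau_dcc override must be in (0, 2]")


@dataclass
class PipelineResult:
    dataset: IonomeDataset
    qc_report: pd.DataFrame
    dce_tables: dict[str, pd.DataFrame]
    clustering_newick: str
    classification: object
    edges: pd.DataFrame
    thresholds: dict[str, dict]
    dcc_tables: dict[str, pd.DataFrame]
    shared_dccs: pd.DataFrame
    reversed_dccs: pd.DataFrame
    group_specific: dict[str, list]
    manifest: dict
    output_dir: Path | None = None


def run_pipeline(config: PipelineConfig, write_outputs: bool = True) -> PipelineResult:
    """Execute every stage in order and (optionally) write the report bundle."""
    from .preprocess import qc_dataset

    config.validate()
    out = Path(config.output_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)

    # -- input ----------------------------------------------------------
    if config.input_path is None:
        syn_seed = stage_seed(config.seed, "synthetic")
        dataset = generate_dataset(default_config(), seed=syn_seed)
        logger.info("synthetic stage: generated %d records (seed %d)",
                    len(dataset.records), syn_seed)
    else:
        dataset = read_ionome_table(config.input_path)
        logger.info("loaded %d records from %s", len(dataset.records),
                    config.input_path)

    # -- QC ---------------------------------------------------------------
    cleaned, qc_report = qc_dataset(dataset, alpha=config.alpha)
    n_replaced = int(qc_report["outlier_index"].notna().sum())
    logger.info("qc stage: %d cells screened, %d outliers replaced",
                len(qc_report), n_replaced)

    # -- thresholds -------------------------------------------------------
    n_rep = int(cleaned.records.groupby(
        ["group", "time_months", "element"]).size().min())
    thr_seed = stage_seed(config.seed, "thresholds")
    thresholds: dict[str, dict] = {}
    if config.tau_scc is None:
        est = simulate_scc_threshold(n_rep, config.alpha, config.inner_reps,
                                     config.outer_reps, seed=thr_seed)
        tau_scc, thresholds["scc"] = est.point, est.to_dict()
    else:
        tau_scc = config.tau_scc
        thresholds["scc"] = {"statistic": "scc", "point": tau_scc,
                             "source": "override"}
    if config.tau_dcc is None:
        est = simulate_dcc_threshold(n_rep, config.alpha, config.inner_reps,
                                     config.outer_reps, seed=thr_seed + 1)
        tau_dcc, thresholds["delta_scc"] = est.point, est.to_dict()
    else:
        tau_dcc = config.tau_dcc
        thresholds["delta_scc"] = {"statistic": "delta_scc", "point": tau_dcc,
                                   "source": "override"}
    logger.info("thresholds: tau_scc=%.3f tau_dcc=%.3f (n=%d)",
                tau_scc, tau_dcc, n_rep)

    # -- DCE ----------------------------------------------------------------
    pairs = [(config.reference_group, config.disease_group),
             (config.disease_group, config.treatment_group)]
    dce_tables = {}
    for ref, comp in pairs:
        dce_tables[f"{comp}_vs_{ref}"] = dce_scan(cleaned, ref, comp,
                                                  alpha=config.alpha)

    # -- clustering / classification -----------------------------------------
    profiles = zscore_rows(profile_matrix(cleaned))
    clustering = cluster_elements(profiles, k=config.cluster_k)
    newick = linkage_to_newick(clustering)
    classification = classify_groups(
        cleaned, config.classification_labels,
        seed=stage_seed(config.seed, "classify"))
    logger.info("classification: cv accuracy %.3f",
                classification.cv_accuracy)

    # -- networks and DCCs ---------------------------------------------------
    edges = scc_tables(cleaned, tau_scc)
    specific = group_specific_edges(edges)
    dcc_ad = dcc_scan(cleaned, config.disease_group, config.reference_group,
                      tau_dcc, tau_scc)
    dcc_se = dcc_scan(cleaned, config.treatment_group, config.disease_group,
                      tau_dcc, tau_scc)
    dcc_tables = {
        f"{config.disease_group}_vs_{config.reference_group}": dcc_ad,
        f"{config.treatment_group}_vs_{config.disease_group}": dcc_se,
    }
    shared, reversed_ = overlap_and_reversed_dccs(dcc_ad, dcc_se)
    logger.info("dcc stage: %d + %d significant DCCs, %d shared, %d reversed",
                int(dcc_ad["significant"].sum()), int(dcc_se["significant"].sum()),
                len(shared), len(reversed_))

    manifest = {
        "ionnet_version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "tau_scc": tau_scc,
        "tau_dcc": tau_dcc,
        "n_records": len(cleaned.records),
        "n_outliers_replaced": n_replaced,
        "thresholds": thresholds,
        "input": config.input_path or "synthetic:default_config",
    }

    result = PipelineResult(
        dataset=cleaned, qc_report=qc_report, dce_tables=dce_tables,
        clustering_newick=newick, classification=classification, edges=edges,
        thresholds=thresholds, dcc_tables=dcc_tables, shared_dccs=shared,
        reversed_dccs=reversed_, group_specific=specific, manifest=manifest,
        output_dir=out if write_outputs else None)

    if write_outputs:
        _write_bundle(result, config, out)
    return result


def _write_bundle(result: PipelineResult, config: PipelineConfig,
                  out: Path) -> None:
    meta = {"seed": config.seed, "tau_scc": result.manifest["tau_scc"],
            "tau_dcc": result.manifest["tau_dcc"]}
    write_ionome_table(result.dataset, out / "cleaned_table.tsv")
    write_tsv(result.qc_report, out / "qc_report.tsv", **meta)
    for name, table in result.dce_tables.items():
        write_tsv(table, out / f"dce_{name}.tsv", **meta)
        write_tsv(dce_summary(table), out / f"dce_{name}_summary.tsv", **meta)
    (out / "dendrogram.nwk").write_text(result.clustering_newick + "\n")
    write_tsv(result.classification.importances.rename("importance")
              .reset_index().rename(columns={"index": "element"}),
              out / "classification_importances.tsv",
              cv_accuracy=result.classification.cv_accuracy, **meta)
    write_tsv(result.edges, out / "edges.tsv", **meta)
    for g in result.dataset.groups:
        for t in result.dataset.timepoints(g):
            sub = result.edges[(result.edges["group"] == g)
                               & (result.edges["time_months"] == t)]
            stem = f"network_{g}_{int(t):02d}m"
            write_sif(sub, out / f"{stem}.sif")
            write_graphml(sub, out / f"{stem}.graphml")
    for name, table in result.dcc_tables.items():
        write_tsv(table, out / f"dcc_{name}.tsv", **meta)
    write_tsv(result.shared_dccs, out / "dcc_shared.tsv", **meta)
    write_tsv(result.reversed_dccs, out / "dcc_reversed.tsv", **meta)
    (out / "group_specific_edges.json").write_text(json.dumps(
        {g: [list(p) for p in pairs] for g, pairs in result.group_specific.items()},
        indent=2))
    (out / "thresholds.json").write_text(json.dumps(result.thresholds, indent=2))
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
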
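"""End-to-end orchestration of the recapitulation analysis.

Binds the modules into the full pipeline: sample QC -> log transform ->
stage-similarity matrices -> GO gene subsets -> subset resampling ->
transition fold changes and recapitulation correlation -> trajectory
classification with zigzag-gene extraction -> GO enrichment.  Every stage
writes TSV outputs into the run directory and the run is summarized in a
manifest; reruns with the same configuration are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .expression_io import (
    read_expression_matrix,
    read_sample_table,
    qc_filter,
    log_transform,
    stage_average,
)
from .ontology import (
    parse_obo,
    read_annotations,
    select_gene_subset,
    DEVELOPMENTAL_PROCESS,
    METABOLIC_PROCESS,
)
from .stage_similarity import pairwise_similarity, embryo_similarity_profile, spearman
from .subset_resampling import resample_metric
from .recapitulation import (
    transition_lfc,
    recapitulation_correlation,
    DEFAULT_LFC_THRESHOLD,
)
from .trajectory_clustering import (
    assign_trajectories,
    select_zigzag_genes,
)
from .enrichment import (
    positive_expression_reference,
    fisher_enrichment,
    enrichment_table,
    DEFAULT_ALPHA,
)

STAGES = (
    "qc",
    "log_transform",
    "similarity",
    "subsets",
    "resampling",
    "recapitulation",
    "trajectories",
    "enrichment",
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "STAGES"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths, QC flags and statistical parameters for one pipeline run."""

    expression_path: str
    samples_path: str
    ontology_path: str | None = None
    annotations_path: str | None = None
    annotations_format: str = "two_column_tsv"
    out_dir: str = "holodev_run"
    exclude_females: bool = True
    drop_duplicates: bool = True
    pseudocount: float = 1.0
    subset_roots: tuple[str, ...] = (DEVELOPMENTAL_PROCESS, METABOLIC_PROCESS)
    B: int = 999
    seed: int = 0
    lcf_threshold: float = DEFAULT_LFC_THRESHOLD
    alpha: float = DEFAULT_ALPHA
    zigzag_criterion: str = "strict_alternating"
    correlation_method: str = "spearman"

    def validate(self) -> None:
        for name in ("expression_path", "samples_path"):
            path = getattr(self, name)
            if not os.path.exists(path):
                raise FileNotFoundError(f"{name}: no such file {path!r}")
        for name in ("ontology_path", "annotations_path"):
            path = getattr(self, name)
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(f"{name}: no such file {path!r}")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, log=None) -> dict:
    """Execute every stage; return the manifest (also written as JSON).

    Any stage failure aborts with :class:`PipelineError` naming the stage.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    out = lambda name: os.path.join(config.out_dir, name)  # noqa: E731
    manifest: dict = {
        "version": __version__,
        "config": {k: v for k, v in asdict(config).items()},
        "stages": [],
        "outputs": {},
    }
    state: dict = {}

    def record(stage: str, t0: float, files: dict) -> None:
        # elapsed time goes to the log only, keeping manifest.json
        # bit-identical across reruns of the same configuration
        manifest["stages"].append(stage)
        manifest["outputs"].update(files)
        if log is not None:
            elapsed = round(time.perf_counter() - t0, 3)
            log(f"[{stage}] done ({elapsed}s)")

    def run_stage(stage: str, fn) -> None:
        t0 = time.perf_counter()
        try:
            files = fn() or {}
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - report stage + cause
            raise PipelineError(stage, exc) from exc
        record(stage, t0, files)

    def stage_qc():
        matrix = read_expression_matrix(config.expression_path)
        samples = read_sample_table(config.samples_path)
        filtered, report = qc_filter(
            matrix,
            samples,
            exclude_females=config.exclude_females,
            drop_duplicates=config.drop_duplicates,
        )
        state["fpkm"] = filtered
        state["samples"] = samples
        path = out("qc_report.tsv")
        pd.DataFrame(report.removed, columns=["sample_id", "reason"]).to_csv(
            path, sep="\t", index=False
        )
        return {"qc_report": path}

    def stage_log():
        state["log"] = log_transform(state["fpkm"], pseudocount=config.pseudocount)
        state["stage_means"] = stage_average(state["log"], state["samples"])
        return {}

    def stage_similarity():
        corr = pairwise_similarity(state["log"])
        path = out("pairwise_similarity.tsv")
        corr.write_tsv(path)
        profile = embryo_similarity_profile(state["log"], state["samples"])
        ppath = out("embryo_similarity.tsv")
        pd.DataFrame(profile, columns=["sample_id", "rho"]).to_csv(
            ppath, sep="\t", index=False
        )
        state["pairwise"] = corr
        return {"pairwise_similarity": path, "embryo_similarity": ppath}

    def stage_subsets():
        state["subsets"] = {}
        if config.ontology_path is None or config.annotations_path is None:
            return {}
        dag = parse_obo(config.ontology_path)
        annotations = read_annotations(
            config.annotations_path, format=config.annotations_format
        )
        state["dag"] = dag
        state["annotations"] = annotations
        rows = []
        genes = set(state["log"].gene_ids)
        for root in config.subset_roots:
            subset = select_gene_subset(annotations, dag, root) & genes
            state["subsets"][root] = subset
            rows.extend({"root": root, "gene_id": g} for g in sorted(subset))
        path = out("gene_subsets.tsv")
        pd.DataFrame(rows, columns=["root", "gene_id"]).to_csv(
            path, sep="\t", index=False
        )
        return {"gene_subsets": path}

    def stage_resampling():
        rows = []
        stage_means = state["stage_means"]

        def embryo_pupa_metric(gene_set):
            sub = stage_means.subset_genes(gene_set)
            return spearman(
                sub.data["embryo"].to_numpy(), sub.data["pupa"].to_numpy()
            )

        for root, subset in state["subsets"].items():
            if len(subset) < 3:
                continue
            res = resample_metric(
                state["log"],
                subset,
                embryo_pupa_metric,
                B=config.B,
                seed=config.seed,
                metric_name=f"embryo_pupa_rho[{root}]",
            )
            rows.append(res.summary_row())
        path = out("resampling.tsv")
        pd.DataFrame(
            rows,
            columns=["metric", "observed", "quantile", "p_value", "B", "seed"],
        ).to_csv(path, sep="\t", index=False)
        state["resampling_rows"] = rows
        return {"resampling": path}

    def stage_recapitulation():
        sm = state["stage_means"]
        lfc_el = transition_lfc(sm, "embryo", "larva", config.lcf_threshold)
        lfc_pa = transition_lfc(sm, "pupa", "adult", config.lcf_threshold)
        per_gene = pd.DataFrame(
            {
                "gene_id": lfc_el.gene_ids,
                "lfc_embryo_larva": lfc_el.lfc,
                "lfc_pupa_adult": lfc_pa.lfc,
                "significant_embryo_larva": lfc_el.significant,
                "significant_pupa_adult": lfc_pa.significant,
            }
        )
        gpath = out("transition_lfc.tsv")
        per_gene.to_csv(gpath, sep="\t", index=False)

        summary = [
            {
                "gene_set": "all",
                "rho": recapitulation_correlation(
                    lfc_el, lfc_pa, method=config.correlation_method
                ),
                "quantile": np.nan,
                "p_value": np.nan,
            }
        ]
        for root, subset in state["subsets"].items():
            if len(subset) < 3:
                continue

            def metric(gene_set):
                return recapitulation_correlation(
                    lfc_el, lfc_pa, subset=gene_set,
                    method=config.correlation_method,
                )

            res = resample_metric(
                state["log"], subset, metric, B=config.B, seed=config.seed,
                metric_name=f"recapitulation[{root}]",
            )
            summary.append(
                {
                    "gene_set": root,
                    "rho": res.observed,
                    "quantile": res.quantile,
                    "p_value": res.p_value,
                }
            )
        spath = out("recapitulation.tsv")
        pd.DataFrame(
            summary, columns=["gene_set", "rho", "quantile", "p_value"]
        ).to_csv(spath, sep="\t", index=False)
        state["recap_summary"] = summary
        return {"transition_lfc": gpath, "recapitulation": spath}

    def stage_trajectories():
        assignment = assign_trajectories(state["stage_means"])
        apath = out("trajectory_assignment.tsv")
        assignment.to_frame().to_csv(apath, sep="\t", index=False)
        zigzag = select_zigzag_genes(assignment, config.zigzag_criterion)
        zpath = out("zigzag_genes.tsv")
        pd.DataFrame(sorted(zigzag), columns=["gene_id"]).to_csv(
            zpath, sep="\t", index=False
        )
        state["zigzag"] = zigzag
        return {"trajectory_assignment": apath, "zigzag_genes": zpath}

    def stage_enrichment():
        if "dag" not in state or "annotations" not in state:
            return {}
        reference = positive_expression_reference(state["fpkm"])
        study = state["zigzag"] & reference
        if not study:
            return {}
        rows = fisher_enrichment(
            study, reference, state["annotations"], state["dag"],
            alpha=config.alpha,
        )
        path = out("enrichment.tsv")
        enrichment_table(rows).to_csv(path, sep="\t", index=False)
        state["enrichment"] = rows
        return {"enrichment": path}

    run_stage("qc", stage_qc)
    run_stage("log_transform", stage_log)
    run_stage("similarity", stage_similarity)
    run_stage("subsets", stage_subsets)
    run_stage("resampling", stage_resampling)
    run_stage("recapitulation", stage_recapitulation)
    run_stage("trajectories", stage_trajectories)
    run_stage("enrichment", stage_enrichment)

    manifest["inputs"] = {
        "expression": _sha256(config.expression_path),
        "samples": _sha256(config.samples_path),
    }
    manifest_path = out("manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["outputs"]["manifest"] = manifest_path
    return manifest
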
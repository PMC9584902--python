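"""Synthetic developmental-transcriptome generator with planted ground truth.

Emulates the structure of a four-stage (embryo, larva, pupa, adult)
whole-body expression dataset: per-gene latent log2 expression levels by
trajectory class, replicate samples with multiplicative log-normal noise on
the FPKM scale (additive Gaussian on log2), an optional egg-signal
contamination of adult-female samples, and a small GO subtree annotating a
slice of the zigzag genes as development-associated.  Every pipeline stage
can therefore be tested against known truth without any external download.

Planted trajectory classes (offsets in log2 units, e = effect size):

========== =======================
class      latent stage offsets
========== =======================
monotone_up    [0, e/3, 2e/3, e]
monotone_down  [0, -e/3, -2e/3, -e]
zigzag_up      [0, e, 0, e]
zigzag_down    [0, -e, 0, -e]
constant       [0, 0, 0, 0]
random         cumulative random steps; the embryo->larva and pupa->adult
               steps are drawn from a bivariate normal with correlation
               ``shared_program_rho`` (the planted recapitulation signal)
========== =======================
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_io import (
    ExpressionMatrix,
    SampleTable,
    MAJOR_STAGES,
    write_expression_matrix,
    write_sample_table,
)
from .ontology import AnnotationMap

GENE_CLASSES = (
    "monotone_up",
    "monotone_down",
    "zigzag_up",
    "zigzag_down",
    "constant",
    "random",
)

# expected trajectory template per planted class (None: no defined template)
CLASS_TEMPLATES = {
    "monotone_up": "+++",
    "monotone_down": "---",
    "zigzag_up": "+-+",
    "zigzag_down": "-+-",
    "constant": "000",
    "random": None,
}

# synthetic GO subtree reusing the canonical biological-process ids so the
# pipeline's default subset roots apply unchanged
SYNTHETIC_OBO_TERMS = [
    ("GO:0008150", "biological_process", None),
    ("GO:0032502", "developmental process", "GO:0008150"),
    ("GO:0048856", "anatomical structure development", "GO:0032502"),
    ("GO:0009790", "embryo development", "GO:0048856"),
    ("GO:0008152", "metabolic process", "GO:0008150"),
    ("GO:0046034", "ATP metabolic process", "GO:0008152"),
]
DEV_LEAF = "GO:0009790"
MET_LEAF = "GO:0046034"

__all__ = [
    "GENE_CLASSES",
    "CLASS_TEMPLATES",
    "SimulationConfig",
    "SimulationTruth",
    "simulate_dataset",
    "write_synthetic_obo",
    "write_fixture",
]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults describe a mid-sized bulk developmental time course: 2,000
    genes, three replicates per stage, log2-scale replicate noise of 0.2
    (≈15% multiplicative), trajectory steps of 2 log2 units, and a modest
    planted recapitulation correlation of 0.3 in the free-trajectory genes.
    """

    n_genes: int = 2000
    class_fractions: dict = field(
        default_factory=lambda: {
            "monotone_up": 0.15,
            "monotone_down": 0.15,
            "zigzag_up": 0.15,
            "zigzag_down": 0.15,
            "constant": 0.10,
            "random": 0.30,
        }
    )
    stage_replicates: dict = field(
        default_factory=lambda: {s: 3 for s in MAJOR_STAGES}
    )
    noise_sd: float = 0.2  # log2 units per replicate
    effect_size: float = 2.0  # log2 units, trajectory step magnitude
    shared_program_rho: float = 0.3
    female_contamination: float = 0.0  # fraction of embryo FPKM mixed in
    dev_annotation_fraction: float = 0.8  # zigzag genes annotated to DEV_LEAF
    met_annotation_fraction: float = 0.3  # other genes annotated to MET_LEAF
    baseline_range: tuple[float, float] = (2.0, 8.0)  # log2 FPKM
    pseudocount: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        fr = self.class_fractions
        unknown = set(fr) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene class(es) {sorted(unknown)}")
        vals = np.array([fr.get(c, 0.0) for c in GENE_CLASSES], dtype=float)
        if (vals < 0).any():
            raise ValueError("class fractions must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-6:
            raise ValueError(f"class fractions sum to {vals.sum()}, not 1")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        for stage in MAJOR_STAGES:
            if self.stage_replicates.get(stage, 0) < 1:
                raise ValueError(f"need >= 1 replicate for stage {stage!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not -1.0 <= self.shared_program_rho <= 1.0:
            raise ValueError("shared_program_rho must be in [-1, 1]")
        if not 0.0 <= self.female_contamination < 1.0:
            raise ValueError("female_contamination must be in [0, 1)")


@dataclass
class SimulationTruth:
    """Ground truth for a simulated dataset."""

    gene_class: dict[str, str]
    latent_levels: pd.DataFrame  # genes x 4 stages, log2 scale
    shared_steps: pd.DataFrame  # random-class genes: embryo->larva, pupa->adult
    sample_stage: dict[str, str]
    sample_sex: dict[str, str]

    def genes_of_class(self, cls: str) -> list[str]:
        return [g for g, c in self.gene_class.items() if c == cls]

    def to_frame(self) -> pd.DataFrame:
        df = self.latent_levels.copy()
        df.insert(0, "class", [self.gene_class[g] for g in df.index])
        df.index.name = "gene_id"
        return df


def _class_counts(config: SimulationConfig) -> dict[str, int]:
    counts = {}
    assigned = 0
    for cls in GENE_CLASSES[:-1]:
        n = int(round(config.class_fractions.get(cls, 0.0) * config.n_genes))
        counts[cls] = n
        assigned += n
    counts["random"] = config.n_genes - assigned
    if counts["random"] < 0:
        # rounding overshoot: shave from the largest class
        biggest = max(GENE_CLASSES[:-1], key=lambda c: counts[c])
        counts[biggest] += counts["random"]
        counts["random"] = 0
    return counts


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleTable, AnnotationMap, SimulationTruth]:
    """Generate one dataset: FPKM matrix, metadata, annotations and truth.

    Fully reproducible from ``config.seed``.  Observed FPKM values are
    2**(latent + noise) − pseudocount floored at 0, so at zero noise the
    analysis log transform (log2(FPKM + pseudocount)) recovers the latent
    levels exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = _class_counts(config)
    e = config.effect_size

    gene_ids: list[str] = []
    gene_class: dict[str, str] = {}
    levels_rows: list[np.ndarray] = []

    offsets = {
        "monotone_up": np.array([0.0, e / 3, 2 * e / 3, e]),
        "monotone_down": np.array([0.0, -e / 3, -2 * e / 3, -e]),
        "zigzag_up": np.array([0.0, e, 0.0, e]),
        "zigzag_down": np.array([0.0, -e, 0.0, -e]),
        "constant": np.zeros(4),
    }
    step_sd = e / 2
    cov = (step_sd**2) * np.array(
        [[1.0, config.shared_program_rho], [config.shared_program_rho, 1.0]]
    )

    i = 0
    for cls in GENE_CLASSES:
        for _ in range(counts[cls]):
            gid = f"g{i:05d}"
            i += 1
            baseline = rng.uniform(*config.baseline_range)
            if cls == "random":
                d13 = rng.multivariate_normal([0.0, 0.0], cov)
                d2 = rng.normal(0.0, step_sd)
                steps = np.array([d13[0], d2, d13[1]])
                offset = np.concatenate([[0.0], np.cumsum(steps)])
            else:
                offset = offsets[cls]
            gene_ids.append(gid)
            gene_class[gid] = cls
            levels_rows.append(baseline + offset)

    # expression cannot fall below zero FPKM: clamp latent log2 levels at 0
    # (log2(0 + pseudocount)) so the back-transform is exactly invertible
    latent = pd.DataFrame(
        np.maximum(np.vstack(levels_rows), 0.0),
        index=gene_ids,
        columns=list(MAJOR_STAGES),
    )

    # samples: per-stage replicates in developmental time order
    sample_ids: list[str] = []
    sample_stage: dict[str, str] = {}
    sample_sex: dict[str, str] = {}
    meta_rows = []
    order = 0
    for stage in MAJOR_STAGES:
        n_rep = config.stage_replicates[stage]
        for r in range(n_rep):
            sid = f"{stage}_{r + 1}"
            if stage == "adult":
                if config.female_contamination > 0:
                    sex = "female" if r % 2 == 1 or n_rep == 1 else "male"
                else:
                    sex = "male"
            else:
                sex = "mixed"
            order += 1
            sample_ids.append(sid)
            sample_stage[sid] = stage
            sample_sex[sid] = sex
            meta_rows.append(
                {
                    "sample_id": sid,
                    "major_stage": stage,
                    "time_order": order,
                    "sex": sex,
                    "tissue": "whole_body",
                }
            )

    n_samples = len(sample_ids)
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
    log2_obs = np.empty((config.n_genes, n_samples))
    stage_idx = {s: k for k, s in enumerate(MAJOR_STAGES)}
    lat = latent.to_numpy()
    for j, sid in enumerate(sample_ids):
        log2_obs[:, j] = lat[:, stage_idx[sample_stage[sid]]] + noise[:, j]
    fpkm = np.maximum(2.0**log2_obs - config.pseudocount, 0.0)

    if config.female_contamination > 0:
        embryo_fpkm = np.maximum(
            2.0 ** lat[:, stage_idx["embryo"]] - config.pseudocount, 0.0
        )
        f = config.female_contamination
        for j, sid in enumerate(sample_ids):
            if sample_sex[sid] == "female":
                fpkm[:, j] = (1 - f) * fpkm[:, j] + f * embryo_fpkm

    matrix = ExpressionMatrix(
        pd.DataFrame(fpkm, index=gene_ids, columns=sample_ids), scale="fpkm"
    )
    samples = SampleTable(pd.DataFrame(meta_rows))

    # annotations: a slice of zigzag genes -> development leaf term;
    # a slice of the remaining genes -> metabolism leaf term
    mapping: dict[str, set[str]] = {}
    zig = [g for g in gene_ids if gene_class[g] in ("zigzag_up", "zigzag_down")]
    n_dev = int(round(config.dev_annotation_fraction * len(zig)))
    for g in rng.choice(zig, size=n_dev, replace=False) if n_dev else []:
        mapping.setdefault(g, set()).add(DEV_LEAF)
    others = [g for g in gene_ids if g not in mapping]
    n_met = int(round(config.met_annotation_fraction * len(others)))
    for g in rng.choice(others, size=n_met, replace=False) if n_met else []:
        mapping.setdefault(g, set()).add(MET_LEAF)
    annotations = AnnotationMap(mapping)

    # planted step truth recorded after the zero clamp so it matches the
    # realizable latent trajectories exactly
    random_genes = [g for g in gene_ids if gene_class[g] == "random"]
    shared = pd.DataFrame(
        {
            "step_embryo_larva": latent.loc[random_genes, "larva"]
            - latent.loc[random_genes, "embryo"],
            "step_pupa_adult": latent.loc[random_genes, "adult"]
            - latent.loc[random_genes, "pupa"],
        }
    )
    truth = SimulationTruth(
        gene_class=gene_class,
        latent_levels=latent,
        shared_steps=shared,
        sample_stage=sample_stage,
        sample_sex=sample_sex,
    )
    return matrix, samples, annotations, truth


def write_synthetic_obo(path) -> None:
    """Write the bundled six-term GO subtree in OBO 1.2 format."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: holodev-synthetic\n")
        for term, name, parent in SYNTHETIC_OBO_TERMS:
            fh.write(f"\n[Term]\nid: {term}\nname: {name}\n")
            if parent is not None:
                fh.write(f"is_a: {parent}\n")


def write_annotations_tsv(annotations: AnnotationMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tgo_id\n")
        for gene in sorted(annotations.gene_to_terms):
            for term in sorted(annotations.gene_to_terms[gene]):
                fh.write(f"{gene}\t{term}\n")


def write_fixture(config: SimulationConfig, out_dir) -> dict[str, str]:
    """Simulate a dataset and write every artifact the pipeline consumes.

    Returns a name -> path map: expression.tsv, samples.tsv, ontology.obo,
    annotations.tsv (two-column dialect) and truth.tsv.
    """
    os.makedirs(out_dir, exist_ok=True)
    matrix, samples, annotations, truth = simulate_dataset(config)
    paths = {
        "expression": os.path.join(out_dir, "expression.tsv"),
        "samples": os.path.join(out_dir, "samples.tsv"),
        "ontology": os.path.join(out_dir, "ontology.obo"),
        "annotations": os.path.join(out_dir, "annotations.tsv"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    write_expression_matrix(matrix, paths["expression"])
    write_sample_table(samples, paths["samples"])
    write_synthetic_obo(paths["ontology"])
    write_annotations_tsv(annotations, paths["annotations"])
    truth.to_frame().to_csv(paths["truth"], sep="\t")
    return paths
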
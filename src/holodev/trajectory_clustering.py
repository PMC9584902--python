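"""Trajectory-template classification and profile clustering.

Across the four major stages there are three transitions, each of which can
go up, stay level, or go down: 3^3 = 27 canonical trajectory templates.
Each gene is assigned to the template whose 4-point level vector its stage
profile correlates with best.  Two of the 27 templates are strictly
alternating "zigzag" trajectories ("+-+" and "-+-"): expression departs from
the embryonic level during the larval stage and reverts to it in the pupa.
Genes in those templates are the candidates for drivers of embryonic-program
recapitulation.

Datasets with dense time courses (>4 time points) are instead clustered
hierarchically with 1 − Spearman correlation as the distance, and zigzag-like
clusters are selected from the standardized stage-mean profiles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .expression_io import ExpressionMatrix, MAJOR_STAGES

TRANSITIONS = ("embryo->larva", "larva->pupa", "pupa->adult")
STEP_CHARS = {1: "+", 0: "0", -1: "-"}

__all__ = [
    "TrajectoryTemplate",
    "TrajectoryAssignment",
    "enumerate_templates",
    "assign_trajectories",
    "select_zigzag_genes",
    "hierarchical_profile_clustering",
    "select_zigzag_clusters",
    "ZIGZAG_STRICT_IDS",
]


@dataclass(frozen=True)
class TrajectoryTemplate:
    """One of the 27 canonical up/same/down trajectories over 3 transitions."""

    steps: tuple[int, int, int]

    @property
    def id(self) -> str:
        return "".join(STEP_CHARS[s] for s in self.steps)

    @property
    def levels(self) -> np.ndarray:
        """4-point level vector: cumulative sum of steps starting at 0."""
        return np.concatenate([[0.0], np.cumsum(self.steps)])

    @property
    def n_changes(self) -> int:
        return sum(1 for s in self.steps if s != 0)


def enumerate_templates() -> list[TrajectoryTemplate]:
    """All 27 templates in canonical order (+ before 0 before − per step)."""
    return [
        TrajectoryTemplate(steps)
        for steps in itertools.product((1, 0, -1), repeat=3)
    ]


# the two strictly alternating zigzag templates: up-down-up and down-up-down
ZIGZAG_STRICT_IDS = ("+-+", "-+-")
# the looser embryo≈pupa family: larva departs, pupa returns, adult free
ZIGZAG_LOOSE_IDS = ("+-+", "+-0", "+--", "-+-", "-+0", "-++")


@dataclass
class TrajectoryAssignment:
    """Per-gene template assignment with its correlation score."""

    assignments: dict[str, tuple[str, float]]
    unassigned: dict[str, str] = field(default_factory=dict)

    def genes_for(self, template_id: str) -> set[str]:
        return {
            g for g, (t, _) in self.assignments.items() if t == template_id
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "template_id": t, "score": s}
            for g, (t, s) in self.assignments.items()
        ]
        return pd.DataFrame(rows, columns=["gene_id", "template_id", "score"])


def assign_trajectories(
    stage_matrix: ExpressionMatrix, min_range: float = 0.5
) -> TrajectoryAssignment:
    """Assign each gene to its best-correlated trajectory template.

    The score is the Pearson correlation between the gene's 4 stage values
    and each template's level vector (Spearman on 4 points is too coarse to
    separate the 27 templates).  The constant template "000" has zero
    variance, so correlation against it is undefined: genes whose total
    dynamic range across the stages (max − min, log2 units) is at most
    ``min_range`` are called flat and assigned to "000" directly; all other
    genes compete among the 26 non-constant templates.  The default of 0.5
    log2 units treats a gene changing less than ~1.4-fold across the whole
    of development as flat.  Ties are broken by fewest non-zero steps, then
    canonical template order.
    """
    if list(stage_matrix.data.columns) != list(MAJOR_STAGES):
        raise ValueError(
            f"expected exactly the 4 stage columns {MAJOR_STAGES}, "
            f"got {list(stage_matrix.data.columns)}"
        )
    templates = enumerate_templates()
    varying = [t for t in templates if t.n_changes > 0]
    # rank tie-break keys: fewer changes first, then canonical order
    order = {t.id: i for i, t in enumerate(templates)}
    level_mat = np.stack([t.levels for t in varying])  # 26 x 4
    centered = level_mat - level_mat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)

    values = stage_matrix.data.to_numpy(dtype=float)
    assignments: dict[str, tuple[str, float]] = {}
    unassigned: dict[str, str] = {}
    gene_ids = stage_matrix.gene_ids
    v_centered = values - values.mean(axis=1, keepdims=True)
    v_norms = np.linalg.norm(v_centered, axis=1)
    # gene x template Pearson correlations in one product
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = (v_centered @ centered.T) / np.outer(v_norms, norms)

    for i, gene in enumerate(gene_ids):
        if np.ptp(values[i]) <= min_range:
            assignments[gene] = ("000", 1.0)
            continue
        row = scores[i]
        best = np.nanmax(row)
        tied = [
            varying[j] for j in np.flatnonzero(row >= best - 1e-12)
        ]
        winner = min(tied, key=lambda t: (t.n_changes, order[t.id]))
        assignments[gene] = (winner.id, float(best))
    return TrajectoryAssignment(assignments, unassigned)


def select_zigzag_genes(
    assignment: TrajectoryAssignment, criterion: str = "strict_alternating"
) -> set[str]:
    """Genes assigned to a zigzag template.

    ``strict_alternating`` keeps the two templates "+-+" and "-+-";
    ``embryo_pupa_family`` additionally admits templates whose third
    transition is flat or continues (6 templates in total).
    """
    if criterion == "strict_alternating":
        ids = ZIGZAG_STRICT_IDS
    elif criterion == "embryo_pupa_family":
        ids = ZIGZAG_LOOSE_IDS
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    out: set[str] = set()
    for tid in ids:
        out |= assignment.genes_for(tid)
    return out


def hierarchical_profile_clustering(
    matrix: ExpressionMatrix, K: int, linkage: str = "average"
) -> tuple[pd.Series, pd.DataFrame, list[str]]:
    """Agglomerative clustering of gene profiles with 1 − Spearman distance.

    Intended for dense time courses (>= 5 time points).  Constant gene
    profiles have undefined correlation and are excluded (returned in the
    report list).  Returns (gene -> cluster label, cluster x sample mean
    profiles, excluded genes).
    """
    if linkage not in ("average", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    if matrix.shape[1] < 5:
        raise ValueError("hierarchical clustering expects >= 5 time points")
    values = matrix.data.to_numpy(dtype=float)
    constant = np.ptp(values, axis=1) == 0
    excluded = [g for g, c in zip(matrix.gene_ids, constant) if c]
    kept = matrix.data.loc[~constant]
    if kept.shape[0] < K:
        raise ValueError(
            f"only {kept.shape[0]} non-constant genes for K={K} clusters"
        )
    ranks = stats.rankdata(kept.to_numpy(dtype=float), axis=1)
    dist = 1.0 - np.corrcoef(ranks)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, 2.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    labels = hierarchy.fcluster(Z, t=K, criterion="maxclust")
    gene_clusters = pd.Series(labels, index=kept.index, name="cluster_id")
    means = kept.groupby(gene_clusters).mean()
    means.index.name = "cluster_id"
    return gene_clusters, means, excluded


def select_zigzag_clusters(
    cluster_means: pd.DataFrame,
    samples,
    delta: float = 0.5,
    epsilon: float = 1.0,
) -> list:
    """Select clusters whose stage profile is embryo≈pupa but larva-shifted.

    Cluster mean profiles are reduced to the 4 major-stage means (using the
    sample table) and standardized to z-scores across the stages.  A cluster
    is zigzag-like when |z_embryo − z_pupa| < delta and
    |z_larva − z_embryo| > epsilon.
    """
    stage_cols = {}
    for stage in MAJOR_STAGES:
        ids = [
            s for s in samples.samples_for_stage(stage)
            if s in cluster_means.columns
        ]
        if not ids:
            raise ValueError(f"no samples for stage {stage!r} in cluster means")
        stage_cols[stage] = cluster_means[ids].mean(axis=1)
    prof = pd.DataFrame(stage_cols)[list(MAJOR_STAGES)]
    z = prof.sub(prof.mean(axis=1), axis=0)
    sd = prof.std(axis=1, ddof=0)
    z = z.div(sd.replace(0.0, np.nan), axis=0)
    selected = []
    for cid, row in z.iterrows():
        if row.isna().any():
            continue  # flat cluster: z undefined
        if (
            abs(row["embryo"] - row["pupa"]) < delta
            and abs(row["larva"] - row["embryo"]) > epsilon
        ):
            selected.append(cid)
    return selected
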
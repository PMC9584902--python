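"""Stage-transition fold changes and the recapitulation correlation.

If metamorphosis re-runs the embryonic differentiation program, the
per-gene expression changes at the pupa-to-adult transition should be
positively correlated with those at the embryo-to-larva transition.  This
module computes log2 fold changes between stage means, flags genes whose
|log2 fold change| exceeds a threshold (default 1.5), correlates the two
transition vectors, and assesses gene-subset effects with the resampling
null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import ExpressionMatrix, SampleTable, stage_average, MAJOR_STAGES
from .stage_similarity import spearman
from .subset_resampling import ResamplingResult, resample_metric

DEFAULT_LFC_THRESHOLD = 1.5

__all__ = [
    "DEFAULT_LFC_THRESHOLD",
    "TransitionLfc",
    "transition_lfc",
    "recapitulation_correlation",
    "recapitulation_subset_test",
]


@dataclass
class TransitionLfc:
    """Per-gene log2 fold change across one stage transition."""

    gene_ids: list[str]
    lfc: np.ndarray
    from_stage: str
    to_stage: str
    threshold: float = DEFAULT_LFC_THRESHOLD

    def __post_init__(self) -> None:
        self.lfc = np.asarray(self.lfc, dtype=float)
        if len(self.gene_ids) != self.lfc.size:
            raise ValueError("gene_ids and lfc lengths disagree")

    @property
    def significant(self) -> np.ndarray:
        """Genes with |log2 fold change| above the threshold."""
        return np.abs(self.lfc) > self.threshold

    def as_series(self) -> pd.Series:
        return pd.Series(self.lfc, index=self.gene_ids)


def transition_lfc(
    stage_matrix: ExpressionMatrix,
    from_stage: str,
    to_stage: str,
    threshold: float = DEFAULT_LFC_THRESHOLD,
) -> TransitionLfc:
    """log2 fold change (to-stage mean − from-stage mean) on the log scale.

    ``stage_matrix`` is the genes x 4 output of :func:`stage_average` on log2
    values, so the difference of columns is a per-gene log2 fold change.
    """
    if stage_matrix.scale != "log":
        raise ValueError("transition_lfc expects log-scale stage means")
    for stage in (from_stage, to_stage):
        if stage not in stage_matrix.data.columns:
            raise ValueError(f"unknown stage label {stage!r}")
    lfc = (
        stage_matrix.data[to_stage] - stage_matrix.data[from_stage]
    ).to_numpy(dtype=float)
    return TransitionLfc(
        gene_ids=stage_matrix.gene_ids,
        lfc=lfc,
        from_stage=from_stage,
        to_stage=to_stage,
        threshold=threshold,
    )


def recapitulation_correlation(
    lfc_el: TransitionLfc,
    lfc_pa: TransitionLfc,
    subset=None,
    method: str = "spearman",
) -> float:
    """Correlation between embryo->larva and pupa->adult fold-change vectors.

    A positive value indicates recapitulation: genes that rise entering the
    larval stage also rise on emergence from the pupa.
    """
    if lfc_el.gene_ids != lfc_pa.gene_ids:
        raise ValueError("the two transitions cover different gene sets")
    x = lfc_el.lfc
    y = lfc_pa.lfc
    if subset is not None:
        keep = np.fromiter(
            (g in set(subset) for g in lfc_el.gene_ids), dtype=bool
        )
        x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"only {x.size} genes after subsetting; need >= 3")
    if method == "spearman":
        return spearman(x, y)
    if method == "pearson":
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return float("nan")
        return float(stats.pearsonr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def recapitulation_subset_test(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    subset,
    B: int = 999,
    seed: int = 0,
    method: str = "spearman",
) -> ResamplingResult:
    """Resampling test: is the subset's recapitulation rho unusually high?

    ``matrix`` must already be on the log scale; stage means and the two
    transition fold-change vectors are computed once, then the correlation
    is re-evaluated on B random same-size gene sets.
    """
    stage_matrix = stage_average(matrix, samples)
    lfc_el = transition_lfc(stage_matrix, "embryo", "larva")
    lfc_pa = transition_lfc(stage_matrix, "pupa", "adult")

    def metric(gene_set) -> float:
        return recapitulation_correlation(lfc_el, lfc_pa, subset=gene_set, method=method)

    return resample_metric(
        matrix, subset, metric, B=B, seed=seed,
        metric_name=f"recapitulation_{method}",
    )
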
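"""Random-gene-set resampling nulls for subset-restricted statistics.

To ask whether a functional gene subset (say, the development-associated
genes) shows an unusually strong correlation, gene sets of the same size
are drawn uniformly at random from the matrix and the statistic is
recomputed on each.  The observed value is then placed on that reference
distribution as a quantile and an add-one empirical p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Collection

import numpy as np

from .expression_io import ExpressionMatrix

__all__ = ["ResamplingResult", "resample_metric"]


@dataclass
class ResamplingResult:
    """Observed statistic against its random-gene-set null distribution.

    ``quantile`` is the fraction of null values <= observed (ties count);
    ``p_value`` is the add-one estimator (1 + #{null >= observed})/(B + 1),
    which never returns 0.
    """

    observed: float
    null_values: np.ndarray
    quantile: float
    p_value: float
    B: int
    seed: int
    metric_name: str = ""

    def summary_row(self) -> dict:
        return {
            "metric": self.metric_name,
            "observed": self.observed,
            "quantile": self.quantile,
            "p_value": self.p_value,
            "B": self.B,
            "seed": self.seed,
        }


def resample_metric(
    matrix: ExpressionMatrix,
    subset: Collection[str],
    metric: Callable[[frozenset], float],
    B: int = 999,
    seed: int = 0,
    metric_name: str = "",
) -> ResamplingResult:
    """Build the random-gene-set null for ``metric`` and place ``subset`` on it.

    ``metric`` maps a gene set to a real number.  B gene sets of size
    ``|subset|`` are drawn uniformly without replacement from all matrix
    genes, independently per replicate, reproducibly from ``seed``.
    """
    genes = np.asarray(matrix.gene_ids, dtype=object)
    subset = frozenset(subset)
    if len(subset) < 3:
        raise ValueError(f"subset has {len(subset)} genes; need at least 3")
    if len(subset) > len(genes):
        raise ValueError(
            f"subset size {len(subset)} exceeds matrix gene count {len(genes)}"
        )
    if B < 1:
        raise ValueError("B must be at least 1")
    missing = subset - set(genes)
    if missing:
        raise ValueError(f"subset genes absent from matrix: {sorted(missing)[:5]}")

    observed = float(metric(subset))
    rng = np.random.default_rng(seed)
    null = np.empty(B, dtype=float)
    k = len(subset)
    for b in range(B):
        draw = rng.choice(genes, size=k, replace=False)
        null[b] = metric(frozenset(draw))
    quantile = float(np.sum(null <= observed) / B)
    p_value = float((1 + np.sum(null >= observed)) / (B + 1))
    return ResamplingResult(
        observed=observed,
        null_values=null,
        quantile=quantile,
        p_value=p_value,
        B=B,
        seed=seed,
        metric_name=metric_name,
    )
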
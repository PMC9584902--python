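"""Spearman stage-similarity matrices and embryo-similarity profiles.

Similarity between developmental samples or stages is measured as the
Spearman rank correlation of log-transformed FPKM profiles across genes.
On a monotonically developing transcriptome the pairwise correlation matrix
is brightest near its diagonal; the signature of metamorphic recapitulation
is an off-diagonal embryo-pupa block.  Correlations can be restricted to a
gene subset (e.g. the development-associated genes) for the subset analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import ExpressionMatrix, SampleTable

__all__ = [
    "CorrelationMatrix",
    "spearman",
    "pairwise_similarity",
    "embryo_similarity_profile",
]


@dataclass
class CorrelationMatrix:
    """Square symmetric Spearman correlation matrix over labelled items."""

    labels: list[str]
    rho: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rho, dtype=float)
        n = len(self.labels)
        if r.shape != (n, n):
            raise ValueError(f"rho shape {r.shape} does not match {n} labels")
        finite = np.isfinite(r)
        if not np.allclose(r[finite], r.T[finite], atol=1e-12):
            raise ValueError("correlation matrix is not symmetric")
        if finite.any() and (np.abs(r[finite]) > 1 + 1e-12).any():
            raise ValueError("correlation outside [-1, 1]")
        self.rho = r

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        out = self.to_frame()
        out.index.name = "label"
        out.to_csv(path, sep="\t")


def spearman(x, y) -> float:
    """Spearman rank correlation with mid-rank ties.

    Returns NaN (the undefined marker) when either vector is constant —
    a silent zero would fake dissimilarity.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def pairwise_similarity(
    matrix: ExpressionMatrix, subset=None
) -> CorrelationMatrix:
    """All-pairs Spearman correlation between sample columns over genes.

    ``subset`` restricts the correlated genes (all genes when omitted);
    fewer than 3 genes after subsetting is an error.
    """
    if matrix.scale != "log":
        raise ValueError("pairwise_similarity expects log-scale values")
    m = matrix if subset is None else matrix.subset_genes(subset)
    if m.shape[0] < 3:
        raise ValueError(
            f"only {m.shape[0]} genes after subsetting; need at least 3"
        )
    values = m.data.to_numpy(dtype=float)
    # rank per column (mid-ranks), then Pearson of the rank columns
    ranks = stats.rankdata(values, axis=0)
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.asarray(rho, dtype=float)
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0, out=rho)
    return CorrelationMatrix(m.sample_ids, rho)


def embryo_similarity_profile(
    matrix: ExpressionMatrix, samples: SampleTable, subset=None
) -> list[tuple[str, float]]:
    """Spearman correlation of every sample against the embryonic reference.

    The reference is the per-gene mean log expression over all embryo
    samples.  Samples are returned in time order.  Aborts if the reference
    or any profile is constant (correlation undefined).
    """
    if matrix.scale != "log":
        raise ValueError("embryo_similarity_profile expects log-scale values")
    m = matrix if subset is None else matrix.subset_genes(subset)
    embryo_ids = [
        s for s in samples.samples_for_stage("embryo") if s in m.data.columns
    ]
    if not embryo_ids:
        raise ValueError("no embryo samples in the matrix")
    reference = m.data[embryo_ids].mean(axis=1).to_numpy()
    out = []
    for sid in samples.ordered_sample_ids():
        if sid not in m.data.columns:
            continue
        rho = spearman(m.data[sid].to_numpy(), reference)
        if np.isnan(rho):
            raise ValueError(
                f"correlation with the embryonic reference undefined for "
                f"{sid!r} (constant profile)"
            )
        out.append((sid, rho))
    return out
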
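"""Expression-matrix and sample-metadata IO, QC filtering and stage averaging.

The pipeline analyses gene-by-sample FPKM matrices spanning the four major
stages of holometabolous development (embryo, larva, pupa, adult).  This
module reads and validates those matrices, applies the sample-level QC rules
used throughout the analysis (removal of adult-female samples, whose
whole-body transcriptomes carry an egg signal, and of bit-identical duplicate
samples), log-transforms FPKM values, and collapses replicates to per-stage
mean profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAJOR_STAGES = ("embryo", "larva", "pupa", "adult")
SEXES = ("female", "male", "mixed", "unknown")

__all__ = [
    "MAJOR_STAGES",
    "SEXES",
    "ExpressionMatrix",
    "SampleTable",
    "QcReport",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_table",
    "write_sample_table",
    "qc_filter",
    "log_transform",
    "stage_average",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a declared scale.

    Parameters
    ----------
    data :
        DataFrame with gene ids as index and sample ids as columns.
    scale :
        ``"fpkm"`` for non-negative linear-scale values, ``"log"`` for
        log2-transformed values (any sign).
    """

    data: pd.DataFrame
    scale: str = "fpkm"

    def __post_init__(self) -> None:
        if self.scale not in ("fpkm", "log"):
            raise ValueError(f"unknown scale {self.scale!r}")
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at gene {idx[i]!r}, sample {cols[j]!r}"
            )
        if self.scale == "fpkm" and values.size and (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative value {values[i, j]} at gene {idx[i]!r}, "
                f"sample {cols[j]!r} (scale=fpkm)"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Restrict to ``genes`` (kept in current row order)."""
        keep = [g for g in self.data.index if g in set(genes)]
        return ExpressionMatrix(self.data.loc[keep], scale=self.scale)


@dataclass
class SampleTable:
    """Per-sample metadata: stage, within-series order, sex and tissue."""

    data: pd.DataFrame

    REQUIRED = ("sample_id", "major_stage", "time_order", "sex", "tissue")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"sample table missing columns {missing}")
        sid = self.data["sample_id"]
        if sid.duplicated().any():
            dup = sid[sid.duplicated()].iloc[0]
            raise ValueError(f"duplicate sample id {dup!r}")
        bad_stage = set(self.data["major_stage"]) - set(MAJOR_STAGES)
        if bad_stage:
            raise ValueError(f"unknown major_stage value(s) {sorted(bad_stage)}")
        bad_sex = set(self.data["sex"]) - set(SEXES)
        if bad_sex:
            raise ValueError(f"unknown sex value(s) {sorted(bad_sex)}")
        self.data = self.data.reset_index(drop=True)

    def stage_of(self, sample_id: str) -> str:
        row = self.data.loc[self.data["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"sample {sample_id!r} not in sample table")
        return row["major_stage"].iloc[0]

    def samples_for_stage(self, stage: str) -> list[str]:
        return list(
            self.data.loc[self.data["major_stage"] == stage, "sample_id"]
        )

    def ordered_sample_ids(self) -> list[str]:
        """Sample ids sorted by time_order (stable on ties)."""
        return list(
            self.data.sort_values("time_order", kind="stable")["sample_id"]
        )


@dataclass
class QcReport:
    """Samples removed by :func:`qc_filter` with the reason for each."""

    removed: list[tuple[str, str]] = field(default_factory=list)

    def removed_ids(self) -> list[str]:
        return [s for s, _ in self.removed]


def read_expression_matrix(path, dialect: str = "genes_in_rows") -> ExpressionMatrix:
    """Read a TSV expression matrix (first column gene ids, header sample ids).

    Values must be non-negative finite numbers on the FPKM scale; duplicate
    gene or sample ids and malformed cells raise with the offending address.
    """
    if dialect != "genes_in_rows":
        raise ValueError(f"unknown dialect {dialect!r}")
    raw = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    try:
        data = raw.astype(float)
    except ValueError:
        for j, col in enumerate(raw.columns):
            for i, cell in enumerate(raw[col]):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric value {cell!r} at gene {raw.index[i]!r}, "
                        f"sample {col!r} in {path}"
                    ) from None
        raise
    return ExpressionMatrix(data, scale="fpkm")


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write the matrix in the TSV dialect read by :func:`read_expression_matrix`."""
    out = matrix.data.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_sample_table(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "tissue": str})
    return SampleTable(df)


def write_sample_table(samples: SampleTable, path) -> None:
    samples.data.to_csv(path, sep="\t", index=False)


def _check_stage_coverage(kept_ids, samples: SampleTable, removed) -> None:
    kept = set(kept_ids)
    for stage in MAJOR_STAGES:
        if not any(s in kept for s in samples.samples_for_stage(stage)):
            reasons = ", ".join(f"{s} ({r})" for s, r in removed) or "none"
            raise ValueError(
                f"QC filtering removed every {stage} sample "
                f"(removed: {reasons}); all four major stages are required"
            )


def qc_filter(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    exclude_females: bool = True,
    drop_duplicates: bool = True,
) -> tuple[ExpressionMatrix, QcReport]:
    """Apply sample-level QC: drop female samples and exact-duplicate columns.

    Adult females carry eggs, so their whole-body transcriptomes correlate
    spuriously with the embryonic state; ``exclude_females`` removes samples
    with sex ``"female"`` (``"mixed"``/``"unknown"`` are retained).
    ``drop_duplicates`` keeps only the first of any group of bit-identical
    expression columns — a proxy for duplicated sequencing runs.

    Raises if filtering would leave any major stage without samples.
    """
    known = set(samples.data["sample_id"])
    missing = [s for s in matrix.sample_ids if s not in known]
    if missing:
        raise ValueError(f"samples absent from metadata: {missing}")

    report = QcReport()
    keep: list[str] = list(matrix.sample_ids)

    if exclude_females:
        female = set(
            samples.data.loc[samples.data["sex"] == "female", "sample_id"]
        )
        for s in [s for s in keep if s in female]:
            report.removed.append((s, "female"))
        keep = [s for s in keep if s not in female]

    if drop_duplicates:
        seen: dict[bytes, str] = {}
        kept2 = []
        for s in keep:
            key = matrix.data[s].to_numpy(dtype=float).tobytes()
            if key in seen:
                report.removed.append((s, f"duplicate of {seen[key]}"))
            else:
                seen[key] = s
                kept2.append(s)
        keep = kept2

    _check_stage_coverage(keep, samples, report.removed)
    return ExpressionMatrix(matrix.data[keep], scale=matrix.scale), report


def log_transform(
    matrix: ExpressionMatrix, pseudocount: float = 1.0, base: int = 2
) -> ExpressionMatrix:
    """Return log_base(FPKM + pseudocount); the default log2(x+1) maps 0 to 0."""
    if matrix.scale != "fpkm":
        raise ValueError("log_transform expects an FPKM-scale matrix")
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    if base != 2:
        raise ValueError("only base 2 is supported")
    data = np.log2(matrix.data.to_numpy(dtype=float) + pseudocount)
    return ExpressionMatrix(
        pd.DataFrame(data, index=matrix.data.index, columns=matrix.data.columns),
        scale="log",
    )


def stage_average(matrix: ExpressionMatrix, samples: SampleTable) -> ExpressionMatrix:
    """Collapse samples to per-major-stage arithmetic means.

    Returns a genes x 4 matrix with columns ordered embryo, larva, pupa,
    adult, computed on the matrix's current scale (the pipeline averages on
    the log scale).
    """
    cols = {}
    for stage in MAJOR_STAGES:
        ids = [s for s in samples.samples_for_stage(stage) if s in matrix.data.columns]
        if not ids:
            raise ValueError(f"no samples for stage {stage!r}")
        cols[stage] = matrix.data[ids].mean(axis=1)
    out = pd.DataFrame(cols, index=matrix.data.index)[list(MAJOR_STAGES)]
    return ExpressionMatrix(out, scale=matrix.scale)
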
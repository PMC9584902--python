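"""GO-term over-representation analysis for selected gene sets.

Zigzag genes (or any study set) are tested for GO-term enrichment against
the positive-expression reference — all genes with positive expression in
at least one sample of the dataset.  Annotations are propagated up the DAG
(a gene annotated to a term is annotated to all its ancestors), each term
with at least one study gene gets a one-sided Fisher exact test
(hypergeometric upper tail), and p-values are Benjamini–Hochberg adjusted
with significance called at an adjusted threshold (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression_io import ExpressionMatrix
from .ontology import AnnotationMap, OntologyDag

DEFAULT_ALPHA = 0.05

__all__ = [
    "DEFAULT_ALPHA",
    "EnrichmentRow",
    "positive_expression_reference",
    "propagate_annotations",
    "fisher_enrichment",
    "enrichment_table",
]


@dataclass
class EnrichmentRow:
    """One tested GO term: 2x2 counts, Fisher p and BH-adjusted p."""

    term: str
    study_count: int
    study_total: int
    pop_count: int
    pop_total: int
    p: float
    p_adj: float
    significant: bool
    direction: str = "enriched"


def positive_expression_reference(matrix: ExpressionMatrix) -> set[str]:
    """Genes with positive expression in at least one sample (FPKM scale)."""
    if matrix.scale != "fpkm":
        raise ValueError("reference set is defined on the FPKM scale")
    positive = (matrix.data.to_numpy(dtype=float) > 0).any(axis=1)
    reference = {g for g, p in zip(matrix.gene_ids, positive) if p}
    if not reference:
        raise ValueError("no genes with positive expression: empty reference")
    return reference


def propagate_annotations(
    annotations: AnnotationMap, dag: OntologyDag
) -> dict[str, set[str]]:
    """Close annotations upward: each gene inherits all ancestor terms.

    Terms absent from the DAG (after alt_id mapping) are dropped here;
    they are visible through ``AnnotationMap.unknown_terms``.
    """
    ancestor_cache: dict[str, set[str]] = {}
    out: dict[str, set[str]] = {}
    for gene, terms in annotations.gene_to_terms.items():
        closed: set[str] = set()
        for t in terms:
            t = dag.canonical(t)
            if t not in dag.graph:
                continue
            if t not in ancestor_cache:
                ancestor_cache[t] = {t} | dag.ancestors(t)
            closed |= ancestor_cache[t]
        if closed:
            out[gene] = closed
    return out


def fisher_enrichment(
    study: set[str],
    reference: set[str],
    annotations: AnnotationMap,
    dag: OntologyDag,
    alpha: float = DEFAULT_ALPHA,
) -> list[EnrichmentRow]:
    """One-sided Fisher enrichment of ``study`` within ``reference``.

    For every term annotating >= 1 study gene (after ancestor propagation)
    the hypergeometric upper-tail probability of drawing at least the
    observed number of term genes in a study-sized sample is computed, then
    BH-adjusted across the tested terms.
    """
    study = set(study)
    reference = set(reference)
    if not study <= reference:
        extra = sorted(study - reference)[:5]
        raise ValueError(f"study genes outside the reference set: {extra}")

    closed = propagate_annotations(annotations, dag)
    pop_total = len(reference)
    study_total = len(study)

    term_pop: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in reference:
        for t in closed.get(gene, ()):
            term_pop[t] = term_pop.get(t, 0) + 1
            if gene in study:
                term_study[t] = term_study.get(t, 0) + 1

    terms = sorted(term_study)  # >= 1 study gene
    if not terms:
        return []
    pvals = np.empty(len(terms))
    for i, t in enumerate(terms):
        k, K = term_study[t], term_pop[t]
        # P[X >= k], X ~ Hypergeom(pop_total, K, study_total)
        pvals[i] = stats.hypergeom.sf(k - 1, pop_total, K, study_total)
    pvals = np.clip(pvals, 0.0, 1.0)
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    rows = [
        EnrichmentRow(
            term=t,
            study_count=term_study[t],
            study_total=study_total,
            pop_count=term_pop[t],
            pop_total=pop_total,
            p=float(pvals[i]),
            p_adj=float(p_adj[i]),
            significant=bool(reject[i]),
        )
        for i, t in enumerate(terms)
    ]
    rows.sort(key=lambda r: (r.p, r.term))
    return rows


def enrichment_table(rows: list[EnrichmentRow]) -> pd.DataFrame:
    cols = [
        "term", "study_count", "study_total", "pop_count", "pop_total",
        "p", "p_adj", "significant", "direction",
    ]
    return pd.DataFrame(
        [{c: getattr(r, c) for c in cols} for r in rows], columns=cols
    )
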
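"""Gene Ontology DAG handling and annotation-driven gene subsets.

The analysis partitions genes into functional subsets — the
development-associated subset (genes annotated to "developmental process",
GO:0032502, or any of its descendants) and the metabolism-associated subset
(GO:0008152 and descendants).  This module parses an OBO ontology into a
child-to-parent DAG, reads gene-to-term annotations in the common formats
(GAF, InterProScan TSV, plain two-column TSV) and computes descendant
closures and the resulting gene subsets.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field

import networkx as nx
import obonet
from Bio.UniProt import GOA

DEVELOPMENTAL_PROCESS = "GO:0032502"
METABOLIC_PROCESS = "GO:0008152"

_GO_ID_RE = re.compile(r"^GO:\d{7}$")

__all__ = [
    "DEVELOPMENTAL_PROCESS",
    "METABOLIC_PROCESS",
    "OntologyDag",
    "AnnotationMap",
    "parse_obo",
    "descendant_closure",
    "read_annotations",
    "select_gene_subset",
]


@dataclass
class OntologyDag:
    """A GO DAG with child-to-parent edges restricted to chosen relations.

    ``graph`` is a networkx DiGraph whose edges point child -> parent; the
    relations kept (``is_a`` always, ``part_of`` by default) are recorded in
    ``relations``.  ``alt_ids`` maps merged alternative ids onto canonical
    term ids.
    """

    graph: nx.DiGraph
    relations: tuple[str, ...] = ("is_a", "part_of")
    alt_ids: dict[str, str] = field(default_factory=dict)

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def roots(self) -> set[str]:
        return {n for n in self.graph.nodes if self.graph.out_degree(n) == 0}

    def canonical(self, term: str) -> str:
        """Map an alt_id to its canonical term id (identity otherwise)."""
        return self.alt_ids.get(term, term)

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable upward from ``term`` (excluding itself)."""
        return nx.descendants(self.graph, term)


def parse_obo(path, relations: tuple[str, ...] = ("is_a", "part_of")) -> OntologyDag:
    """Parse an OBO 1.2 stanza file into an :class:`OntologyDag`.

    Obsolete terms are excluded; ``alt_id`` entries are mapped onto their
    canonical term.  Edges to undeclared terms and cycles are hard errors.
    """
    multi = obonet.read_obo(path, ignore_obsolete=True)
    declared = {n for n, d in multi.nodes(data=True) if d.get("name") is not None}
    graph = nx.DiGraph()
    graph.add_nodes_from(declared)
    for child, parent, rel in multi.edges(keys=True):
        if rel not in relations:
            continue
        for endpoint in (child, parent):
            if endpoint not in declared:
                raise ValueError(
                    f"edge {child} -[{rel}]-> {parent} references "
                    f"undeclared term {endpoint!r}"
                )
        graph.add_edge(child, parent, relation=rel)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ValueError(f"ontology contains a cycle: {cycle}")
    alt_ids: dict[str, str] = {}
    for node, data in multi.nodes(data=True):
        if node not in declared:
            continue
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
    return OntologyDag(graph, relations=tuple(relations), alt_ids=alt_ids)


def descendant_closure(dag: OntologyDag, root: str) -> set[str]:
    """The root term together with every term below it in the DAG.

    A term is in the closure iff its parent chain (over the DAG's relations)
    reaches ``root``; the root itself is always included.
    """
    root = dag.canonical(root)
    if root not in dag.graph:
        raise KeyError(f"unknown ontology term {root!r}")
    # edges point child -> parent, so descendants of root are the nodes from
    # which root is reachable
    return {root} | nx.ancestors(dag.graph, root)


@dataclass
class AnnotationMap:
    """Direct (pre-closure) gene-to-GO-term annotations."""

    gene_to_terms: dict[str, set[str]]
    skipped: list[str] = field(default_factory=list)

    @property
    def genes(self) -> set[str]:
        return set(self.gene_to_terms)

    def terms_for(self, gene: str) -> set[str]:
        return self.gene_to_terms.get(gene, set())

    def unknown_terms(self, dag: OntologyDag) -> set[str]:
        """Annotated term ids absent from the DAG (after alt_id mapping)."""
        out = set()
        for terms in self.gene_to_terms.values():
            for t in terms:
                if dag.canonical(t) not in dag.graph:
                    out.add(t)
        return out


def _add(mapping: dict[str, set[str]], skipped: list[str], gene: str, term: str) -> None:
    term = term.strip()
    if not _GO_ID_RE.match(term):
        warnings.warn(f"skipping malformed GO id {term!r} for gene {gene!r}")
        skipped.append(term)
        return
    mapping.setdefault(gene, set()).add(term)


def read_annotations(path, format: str = "gaf") -> AnnotationMap:
    """Read gene-to-GO annotations.

    ``gaf``
        GAF 2.x; uses the DB Object Symbol and GO ID columns, skipping
        NOT-qualified associations.
    ``interproscan_tsv``
        InterProScan tabular output; GO ids are taken from the
        pipe-separated GO column (the last ``GO:``-containing field).
    ``two_column_tsv``
        Plain ``gene<TAB>GO:NNNNNNN`` pairs (header optional).

    Malformed GO ids are skipped with a warning and counted in ``skipped``.
    """
    mapping: dict[str, set[str]] = {}
    skipped: list[str] = []
    if format == "gaf":
        with open(path) as handle:
            for rec in GOA.gafiterator(handle):
                if any("NOT" in q for q in rec.get("Qualifier", [])):
                    continue
                _add(mapping, skipped, rec["DB_Object_Symbol"], rec["GO_ID"])
    elif format == "interproscan_tsv":
        with open(path) as handle:
            for row in csv.reader(handle, delimiter="\t"):
                if not row:
                    continue
                gene = row[0]
                go_fields = [f for f in row[1:] if "GO:" in f]
                if not go_fields:
                    continue
                for term in go_fields[-1].split("|"):
                    if term and term != "-":
                        _add(mapping, skipped, gene, term)
    elif format == "two_column_tsv":
        with open(path) as handle:
            for row in csv.reader(handle, delimiter="\t"):
                if len(row) < 2 or row[0] in ("gene_id", "gene"):
                    continue
                _add(mapping, skipped, row[0], row[1])
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    return AnnotationMap(mapping, skipped=skipped)


def select_gene_subset(
    annotations: AnnotationMap, dag: OntologyDag, root: str
) -> set[str]:
    """Genes with at least one direct annotation inside ``root``'s closure.

    This is how the development- and metabolism-associated subsets are
    built: a gene belongs to the subset of ``root`` if it is annotated to
    ``root`` itself or to any descendant term.
    """
    closure = descendant_closure(dag, root)
    subset = {
        gene
        for gene, terms in annotations.gene_to_terms.items()
        if any(dag.canonical(t) in closure for t in terms)
    }
    if not subset:
        warnings.warn(f"no genes annotated within the closure of {root}")
    return subset
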
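"""Gene Ontology DAGs and gene annotations.

Terms are connected by ``is_a`` edges (child -> parent); annotations at a
term are understood to hold for all of its ancestors, which is what makes
up-propagation of sparse leaf annotations meaningful.  The depth of a term
is its shortest ``is_a`` distance from the namespace root (root = level 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property

import networkx as nx
import obonet
from Bio.UniProt import GOA

logger = logging.getLogger(__name__)

__all__ = [
    "GoDag",
    "AnnotationMap",
    "read_obo",
    "write_obo",
    "read_gaf",
    "write_gaf",
    "term_level",
]

_ASPECT_TO_NAMESPACE = {
    "P": "biological_process",
    "F": "molecular_function",
    "C": "cellular_component",
}
_NAMESPACE_TO_ASPECT = {v: k for k, v in _ASPECT_TO_NAMESPACE.items()}


class OntologyError(ValueError):
    pass


class GafFormatError(ValueError):
    pass


@dataclass
class GoDag:
    """Directed acyclic ``is_a`` graph of ontology terms.

    ``graph`` holds one directed edge child -> parent per ``is_a``
    relation; node attribute ``namespace`` records the sub-ontology.
    """

    graph: nx.DiGraph

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise OntologyError(f"is_a cycle involving term {cycle[0][0]!r}")

    @classmethod
    def from_edges(cls, edges, namespace: str = "biological_process", extra_terms=()) -> "GoDag":
        """Build a single-namespace DAG from (child, parent) pairs."""
        g = nx.DiGraph()
        g.add_nodes_from(extra_terms)
        g.add_edges_from(edges)
        nx.set_node_attributes(g, namespace, "namespace")
        return cls(g)

    @property
    def term_ids(self) -> list[str]:
        return sorted(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def roots(self) -> list[str]:
        """Terms with no is_a parent (one per namespace in a full GO)."""
        return sorted(n for n in self.graph.nodes if self.graph.out_degree(n) == 0)

    def namespace(self, term: str) -> str | None:
        return self.graph.nodes[term].get("namespace")

    def parents(self, term: str) -> list[str]:
        return sorted(self.graph.successors(term))

    def children(self, term: str) -> list[str]:
        return sorted(self.graph.predecessors(term))

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable from ``term`` by is_a edges (excluding itself)."""
        return set(nx.descendants(self.graph, term))

    @cached_property
    def _levels(self) -> dict[str, int]:
        levels: dict[str, int] = {}
        for root in self.roots:
            ns = self.namespace(root)
            # walk root -> children, i.e. along reversed is_a edges
            lengths = nx.single_source_shortest_path_length(self.graph.reverse(copy=False), root)
            for term, depth in lengths.items():
                if self.namespace(term) != ns:
                    continue
                if term not in levels or depth < levels[term]:
                    levels[term] = depth
        return levels

    def level(self, term: str) -> int:
        """Shortest is_a distance from the namespace root; root is level 0."""
        if term not in self.graph:
            raise OntologyError(f"unknown term {term!r}")
        try:
            return self._levels[term]
        except KeyError:
            raise OntologyError(f"term {term!r} does not reach a namespace root") from None

    def terms_at_level(self, level: int) -> list[str]:
        return sorted(t for t, l in self._levels.items() if l == level)


def term_level(dag: GoDag, term: str) -> int:
    """Depth of ``term``: length of the shortest is_a path from the root."""
    return dag.level(term)


def read_obo(path) -> GoDag:
    """Read an OBO 1.2 flat file, keeping only ``is_a`` edges.

    Obsolete terms are excluded; other relationship types (``part_of``,
    ``regulates`` ...) are ignored.  A cyclic ``is_a`` structure raises
    :class:`OntologyError` naming one cycle member.
    """
    multi = obonet.read_obo(path, ignore_obsolete=True)
    g = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        g.add_node(node, namespace=data.get("namespace"), name=data.get("name"))
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            g.add_edge(child, parent)
    return GoDag(g)


def write_obo(dag: GoDag, path) -> None:
    """Write a minimal OBO 1.2 file readable by :func:`read_obo`."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        fh.write("ontology: go\n")
        for term in dag.term_ids:
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            name = dag.graph.nodes[term].get("name") or term
            fh.write(f"name: {name}\n")
            ns = dag.namespace(term)
            if ns:
                fh.write(f"namespace: {ns}\n")
            for parent in dag.parents(term):
                fh.write(f"is_a: {parent}\n")


@dataclass
class AnnotationMap:
    """Bipartite gene <-> term incidence with mutually consistent views."""

    gene_to_terms: dict[str, set[str]] = field(default_factory=dict)
    term_to_genes: dict[str, set[str]] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs) -> "AnnotationMap":
        am = cls()
        for gene, term in pairs:
            am.add(gene, term)
        return am

    def add(self, gene: str, term: str) -> None:
        self.gene_to_terms.setdefault(gene, set()).add(term)
        self.term_to_genes.setdefault(term, set()).add(gene)

    @property
    def genes(self) -> list[str]:
        return sorted(self.gene_to_terms)

    @property
    def terms(self) -> list[str]:
        return sorted(self.term_to_genes)

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return {(g, t) for g, ts in self.gene_to_terms.items() for t in ts}

    def n_pairs(self) -> int:
        return sum(len(ts) for ts in self.gene_to_terms.values())

    def genes_of(self, term: str) -> set[str]:
        return set(self.term_to_genes.get(term, set()))

    def terms_of(self, gene: str) -> set[str]:
        return set(self.gene_to_terms.get(gene, set()))

    def restrict(self, genes=None, terms=None) -> "AnnotationMap":
        """Sub-map keeping only the given genes and/or terms."""
        gset = None if genes is None else set(genes)
        tset = None if terms is None else set(terms)
        return AnnotationMap.from_pairs(
            (g, t)
            for g, t in self.pairs
            if (gset is None or g in gset) and (tset is None or t in tset)
        )

    def restrict_pairs(self, pairs) -> "AnnotationMap":
        keep = set(pairs)
        return AnnotationMap.from_pairs(p for p in self.pairs if p in keep)


def read_gaf(
    path,
    dag: GoDag,
    namespace_filter: str = "biological_process",
    exclude_evidence: tuple[str, ...] = (),
    id_field: str = "DB_Object_ID",
) -> AnnotationMap:
    """Read a GAF 2.x annotation file against a loaded DAG.

    Rows with a NOT qualifier are dropped, as are rows whose term lies
    outside ``namespace_filter`` or is absent from ``dag`` (the latter with
    a warning count).  ``exclude_evidence`` drops the listed evidence codes
    (e.g. ``("IEA",)``); by default all are retained.
    """
    # light structural pre-check so parse errors carry a line number
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            if len(line.rstrip("\n").split("\t")) < 15:
                raise GafFormatError(f"unparseable GAF line {lineno}: fewer than 15 columns")
    am = AnnotationMap()
    missing = 0
    with open(path) as fh:
        for rec in GOA.gafiterator(fh):
            if "NOT" in rec.get("Qualifier", []):
                continue
            if rec.get("Evidence") in exclude_evidence:
                continue
            term = rec["GO_ID"]
            if term not in dag:
                missing += 1
                continue
            ns = dag.namespace(term) or _ASPECT_TO_NAMESPACE.get(rec.get("Aspect", ""), None)
            if ns != namespace_filter:
                continue
            am.add(rec[id_field], term)
    if missing:
        logger.warning("read_gaf: dropped %d row(s) whose term is absent from the DAG", missing)
    return am


def write_gaf(am: AnnotationMap, dag: GoDag, path, db: str = "MIHC", taxon: str = "taxon:4932") -> None:
    """Write annotations as a minimal GAF 2.2 file (round-trips with read_gaf)."""
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for gene, term in sorted(am.pairs):
            aspect = _NAMESPACE_TO_ASPECT.get(dag.namespace(term) or "", "P")
            cols = [
                db, gene, gene, "involved_in", term, "REF:0000001", "EXP", "",
                aspect, gene, "", "gene", taxon, "20140312", db, "", "",
            ]
            fh.write("\t".join(cols) + "\n")
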
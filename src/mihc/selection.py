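"""Non-noise gene selection by per-term correlation cliques.

Genes taking part in the same biological process are expected to be
co-expressed, so for each annotated term we keep only a clique of mutually,
significantly correlated genes.  Per term: build the graph whose vertices
are the term's genes and whose edges join significantly correlated pairs,
then take a greedy maximal clique.  The union of the retained cliques
restricts the expression matrix and the annotation map to the "non-noise
system" that all downstream learning-system construction works on.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .expression import TimeCourseMatrix
from .ontology import AnnotationMap

logger = logging.getLogger(__name__)

__all__ = [
    "pearson_r",
    "is_significant",
    "CorrelationGraph",
    "build_term_graph",
    "greedy_clique",
    "NonNoiseSystem",
    "build_non_noise_system",
]


class ConstantProfileError(ValueError):
    """Correlation is undefined for a constant expression profile."""


def pearson_r(x, y) -> float:
    """Sample Pearson correlation of two equal-length profiles (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("profiles must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantProfileError("correlation undefined for a constant profile")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    return max(-1.0, min(1.0, r))


def is_significant(r: float, n: int, alpha: float = 0.05) -> bool:
    """Two-sided t-test of a Pearson correlation: is p < alpha?

    Uses t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.  A perfect
    correlation (|r| = 1) is always significant.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if abs(r) >= 1.0:
        return True
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return bool(p < alpha)


@dataclass
class CorrelationGraph:
    """Significant-correlation graph over the genes of one term."""

    term: str
    graph: nx.Graph  # nodes = gene ids; edge attribute "r"

    @property
    def vertices(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}


def build_term_graph(
    term: str,
    annot: AnnotationMap,
    expr: TimeCourseMatrix,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> CorrelationGraph:
    """Graph of the term's genes with edges between significant pairs.

    Vertices are the genes annotated to ``term`` that are present in
    ``expr``.  With ``bonferroni=True`` the per-pair alpha is divided by
    the number of pairs tested for this term.  Constant profiles yield no
    edges (their correlation is undefined).
    """
    genes = sorted(annot.genes_of(term) & set(expr.gene_ids))
    g = nx.Graph()
    g.add_nodes_from(genes)
    n_pairs = len(genes) * (len(genes) - 1) // 2
    a = alpha / n_pairs if (bonferroni and n_pairs) else alpha
    n = expr.n_timepoints
    for u, v in itertools.combinations(genes, 2):
        try:
            r = pearson_r(expr.profile(u), expr.profile(v))
        except ConstantProfileError:
            continue
        if is_significant(r, n, a):
            g.add_edge(u, v, r=r)
    return CorrelationGraph(term=term, graph=g)


def greedy_clique(cg: CorrelationGraph) -> set[str]:
    """Greedy maximal clique of a correlation graph.

    Starts from the highest-degree vertex and repeatedly adds, among the
    remaining vertices adjacent to every current member, the one of highest
    degree within that candidate set; ties break lexicographically by gene
    id.  The result is a clique that is maximal (no vertex of the graph is
    adjacent to all members) and deterministic.
    """
    g = cg.graph
    if g.number_of_nodes() == 0:
        return set()

    def best(candidates: set[str], sub: nx.Graph) -> str:
        return min(candidates, key=lambda v: (-sub.degree(v), v))

    start = best(set(g.nodes), g)
    clique = {start}
    candidates = set(g.adj[start])
    while candidates:
        sub = g.subgraph(candidates)
        v = best(candidates, sub)
        clique.add(v)
        candidates &= set(g.adj[v])
    return clique


@dataclass
class NonNoiseSystem:
    """Per-term cliques with the restricted expression matrix and annotations."""

    term_cliques: dict[str, frozenset]
    expression: TimeCourseMatrix
    annotations: AnnotationMap

    @property
    def terms(self) -> list[str]:
        return sorted(self.term_cliques)

    @property
    def genes(self) -> list[str]:
        return list(self.expression.gene_ids)


def build_non_noise_system(
    expr: TimeCourseMatrix,
    annot: AnnotationMap,
    alpha: float = 0.05,
    min_clique: int = 2,
    bonferroni: bool = False,
) -> NonNoiseSystem:
    """Restrict expression and annotation to per-term correlation cliques.

    Terms whose greedy clique has fewer than ``min_clique`` genes are
    dropped.  The retained expression submatrix is the union of all clique
    genes; the annotation map keeps exactly the retained (gene, term)
    pairs.
    """
    if min_clique < 1:
        raise ValueError("min_clique must be >= 1")
    cliques: dict[str, frozenset] = {}
    for term in annot.terms:
        cg = build_term_graph(term, annot, expr, alpha=alpha, bonferroni=bonferroni)
        clique = greedy_clique(cg)
        if len(clique) >= min_clique:
            cliques[term] = frozenset(clique)
        else:
            logger.debug("term %s dropped (clique size %d < %d)", term, len(clique), min_clique)
    if not cliques:
        raise ValueError(
            "no term retained a clique of size >= "
            f"{min_clique}; consider a larger alpha or a smaller min_clique"
        )
    genes = sorted(set().union(*cliques.values()))
    sub_expr = expr.subset(genes)
    sub_annot = AnnotationMap.from_pairs(
        (g, t) for t, members in cliques.items() for g in sorted(members)
    )
    return NonNoiseSystem(term_cliques=cliques, expression=sub_expr, annotations=sub_annot)
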
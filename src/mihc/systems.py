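"""Multi-label learning-system construction: GNC, GOLC and MIHC.

A learning system turns raw (gene, term) annotations into classes large
enough to train on.  Three constructions are provided:

* **GNC** (gene-number clustering): annotations up-propagate along the GO
  DAG, bottom-up, until every surviving term holds at least ``lam`` genes.
* **GOLC** (GO-level clustering): every annotation is re-assigned to the
  ancestors of its term sitting exactly at DAG level ``iota``.
* **MIHC** (multi-instance hierarchical clustering): each term of the
  non-noise system is a bag whose instances are its clique genes'
  expression profiles; bags are merged agglomeratively under a
  Hausdorff-family bag distance built on 1 - Pearson correlation, and the
  merging stops once the closest pair of clusters is farther apart than a
  terminal factor ``tau``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .ontology import AnnotationMap, GoDag, term_level
from .selection import NonNoiseSystem

logger = logging.getLogger(__name__)

__all__ = [
    "LearningSystem",
    "Dendrogram",
    "gnc",
    "golc",
    "bag_distance",
    "instance_distances",
    "mihc",
]

BAG_DISTANCE_MODES = ("avg_hausdorff", "max_hausdorff", "min_hausdorff")


@dataclass
class SystemClass:
    """One class of a learning system: a set of terms and its member genes."""

    term_ids: frozenset
    genes: frozenset

    @property
    def label(self) -> str:
        return "+".join(sorted(self.term_ids))


@dataclass
class LearningSystem:
    """Classes plus the binary genes x classes label matrix."""

    classes: list[SystemClass]
    gene_ids: list[str]
    method_tag: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c in self.classes:
            if not c.genes:
                raise ValueError("every class must contain at least one gene")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def label_matrix(self) -> np.ndarray:
        """Binary matrix, ``[g, c] = 1`` iff gene g belongs to class c."""
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        y = np.zeros((len(self.gene_ids), len(self.classes)), dtype=int)
        for j, c in enumerate(self.classes):
            for g in c.genes:
                y[idx[g], j] = 1
        return y


# ---------------------------------------------------------------------------
# GNC: up-propagate until every class holds at least lam genes
# ---------------------------------------------------------------------------

def gnc(annot: AnnotationMap, dag: GoDag, lam: int) -> LearningSystem:
    """Gene-number clustering.

    Working bottom-up (deepest DAG levels first, recomputed after each
    pass), every term with fewer than ``lam`` genes transfers its genes to
    all of its parents and is removed; edges are re-wired so its children
    attach to its parents.  A root left with fewer than ``lam`` genes is
    dropped and its genes reported unplaced.  Classes are the surviving
    terms.
    """
    if lam < 1:
        raise ValueError("lam must be >= 1")
    work = dag.graph.copy()
    genes: dict[str, set] = {t: set(annot.genes_of(t)) for t in work.nodes}
    changed = True
    while changed:
        changed = False
        levels = GoDag(work)._levels
        order = sorted(work.nodes, key=lambda t: (-levels.get(t, 0), t))
        for term in order:
            if term not in work or len(genes[term]) >= lam:
                continue
            parents = list(work.successors(term))
            if not parents:
                continue  # under-populated root; handled after the passes
            for p in parents:
                genes[p] |= genes[term]
            for child in list(work.predecessors(term)):
                for p in parents:
                    if child != p:
                        work.add_edge(child, p)
            work.remove_node(term)
            del genes[term]
            changed = True
    unplaced: set = set()
    survivors = []
    for term in sorted(work.nodes):
        if len(genes[term]) >= lam:
            survivors.append(term)
        elif work.out_degree(term) == 0 and genes[term]:
            unplaced |= genes[term]
            logger.warning(
                "gnc: root %s dropped with %d gene(s) unplaced", term, len(genes[term])
            )
    if not survivors:
        raise ValueError("gnc produced no class; lower lam or provide more annotations")
    classes = [SystemClass(frozenset({t}), frozenset(genes[t])) for t in survivors]
    gene_ids = sorted(set().union(*(c.genes for c in classes)))
    return LearningSystem(
        classes=classes, gene_ids=gene_ids, method_tag="GNC",
        params={"lam": lam, "unplaced_genes": sorted(unplaced - set(gene_ids))},
    )


# ---------------------------------------------------------------------------
# GOLC: up-propagate to a fixed DAG level
# ---------------------------------------------------------------------------

def golc(annot: AnnotationMap, dag: GoDag, iota: int) -> LearningSystem:
    """GO-level clustering.

    Every (gene, term) annotation is re-assigned to each ancestor of the
    term (the term itself included) whose level equals ``iota``.  Terms
    lying above level ``iota`` contribute nothing.  Classes are the
    level-``iota`` terms that received at least one gene.
    """
    if iota < 1:
        raise ValueError("iota must be >= 1")
    class_genes: dict[str, set] = {}
    for gene, term in annot.pairs:
        if term not in dag:
            continue
        targets = [
            t for t in (dag.ancestors(term) | {term}) if term_level(dag, t) == iota
        ]
        for t in targets:
            class_genes.setdefault(t, set()).add(gene)
    if not class_genes:
        raise ValueError(f"no annotation reaches a level-{iota} term")
    classes = [
        SystemClass(frozenset({t}), frozenset(gs))
        for t, gs in sorted(class_genes.items())
    ]
    gene_ids = sorted(set().union(*(c.genes for c in classes)))
    return LearningSystem(
        classes=classes, gene_ids=gene_ids, method_tag="GOLC", params={"iota": iota}
    )


# ---------------------------------------------------------------------------
# MIHC: agglomerative clustering of multi-instance bags
# ---------------------------------------------------------------------------

def instance_distances(profiles: np.ndarray) -> np.ndarray:
    """Pairwise instance distance 1 - Pearson r between profile rows.

    Constant profiles have undefined correlation; their distances are set
    to the maximum (2.0) and a warning is logged.
    """
    profiles = np.asarray(profiles, dtype=float)
    const = np.ptp(profiles, axis=1) == 0
    if const.any():
        logger.warning("instance_distances: %d constant profile(s); distance set to 2.0",
                       int(const.sum()))
    safe = profiles.copy()
    safe[const] = np.arange(profiles.shape[1])  # placeholder rows, overwritten below
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.corrcoef(safe)
    d = np.clip(d, 0.0, 2.0)
    d[const, :] = 2.0
    d[:, const] = 2.0
    np.fill_diagonal(d, 0.0)
    return d


def _bag_from_matrix(d: np.ndarray, a, b, mode: str) -> float:
    sub = d[np.ix_(list(a), list(b))]
    if mode == "avg_hausdorff":
        return float((sub.min(axis=1).sum() + sub.min(axis=0).sum()) / (sub.shape[0] + sub.shape[1]))
    if mode == "max_hausdorff":
        return float(max(sub.min(axis=1).max(), sub.min(axis=0).max()))
    if mode == "min_hausdorff":
        return float(sub.min())
    raise ValueError(f"unknown bag-distance mode {mode!r}")


def bag_distance(a: np.ndarray, b: np.ndarray, mode: str = "avg_hausdorff") -> float:
    """Hausdorff-family distance between two bags of expression profiles.

    The instance distance is ``d(x, y) = 1 - pearson_r(x, y)`` (range
    [0, 2]).  With row minima ``m_x = min_y d(x, y)`` and column minima
    ``m_y = min_x d(x, y)``:

    * ``avg_hausdorff`` -- ``(sum m_x + sum m_y) / (|a| + |b|)``
    * ``max_hausdorff`` -- ``max(max m_x, max m_y)``
    * ``min_hausdorff`` -- the smallest cross-pair distance

    All modes are symmetric and non-negative; the average variant is zero
    on identical bags.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("bags must be non-empty")
    stacked = np.vstack([a, b])
    d = instance_distances(stacked)
    return _bag_from_matrix(d, range(len(a)), range(len(a), len(a) + len(b)), mode)


@dataclass
class Dendrogram:
    """Merge history of the agglomeration.

    ``merges`` lists ``(cluster_a, cluster_b, height, new_cluster_id)``
    with initial clusters numbered 0..n-1 (in ``leaf_names`` order) and new
    clusters numbered onward from n, as in scipy linkage matrices.
    """

    leaf_names: list[str]
    merges: list[tuple[int, int, float, int]]

    def to_newick(self) -> str:
        """Newick string with merge heights as node heights (branch lengths
        are height differences; leaves sit at height 0)."""
        n = len(self.leaf_names)
        node: dict[int, str] = {i: self.leaf_names[i] for i in range(n)}
        height = {i: 0.0 for i in range(n)}
        for a, b, h, new in self.merges:
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            node[new] = f"({node[a]}:{la:g},{node[b]}:{lb:g})"
            height[new] = h
        roots = sorted(set(node) - {a for a, b, _, _ in self.merges} - {b for _, b, _, _ in self.merges})
        if len(roots) == 1:
            return node[roots[0]] + ";"
        inner = ",".join(f"{node[r]}:0" for r in roots)
        return f"({inner});"


def mihc(
    nns: NonNoiseSystem,
    stop_tau: float | None = None,
    mode: str = "avg_hausdorff",
) -> tuple[LearningSystem, Dendrogram]:
    """Multi-instance hierarchical clustering of the non-noise terms.

    Each retained term starts as one cluster whose instances are the
    expression profiles of its clique genes.  The two clusters at minimum
    bag distance are merged (the merged instance set is the union) until
    the minimum pairwise distance exceeds the terminal factor ``stop_tau``
    or a single cluster remains.  ``stop_tau=None`` uses the data-adaptive
    default: the mean of the initial pairwise bag-distance matrix, which
    keeps the method free of user-set parameters.  Ties break on the
    lowest pair of cluster indices.

    Classes are the final clusters; each class's gene set is the union of
    its member terms' cliques, so the system's genes are exactly the
    non-noise genes.
    """
    if mode not in BAG_DISTANCE_MODES:
        raise ValueError(f"unknown bag-distance mode {mode!r}")
    terms = nns.terms
    if not terms:
        raise ValueError("empty non-noise system")
    gene_index = {g: i for i, g in enumerate(nns.expression.gene_ids)}
    d = instance_distances(nns.expression.values)
    bags: dict[int, list[int]] = {
        i: sorted(gene_index[g] for g in nns.term_cliques[t]) for i, t in enumerate(terms)
    }
    members: dict[int, set] = {i: {terms[i]} for i in range(len(terms))}
    if len(terms) == 1:
        cls = [SystemClass(frozenset(terms), frozenset(nns.term_cliques[terms[0]]))]
        ls = LearningSystem(cls, list(nns.expression.gene_ids), "MIHC",
                            {"stop_tau": stop_tau, "mode": mode})
        return ls, Dendrogram(leaf_names=list(terms), merges=[])

    dist: dict[tuple[int, int], float] = {}
    active = sorted(bags)
    for i, j in itertools.combinations(active, 2):
        dist[(i, j)] = _bag_from_matrix(d, bags[i], bags[j], mode)
    if stop_tau is None:
        stop_tau = float(np.mean(list(dist.values())))
    merges: list[tuple[int, int, float, int]] = []
    next_id = len(terms)
    while len(active) > 1:
        h, a, b = min((dist[(i, j)], i, j) for i, j in itertools.combinations(active, 2))
        if h > stop_tau:
            break
        bags[next_id] = sorted(set(bags[a]) | set(bags[b]))
        members[next_id] = members[a] | members[b]
        merges.append((a, b, h, next_id))
        active = [x for x in active if x not in (a, b)]
        for x in active:
            key = (min(x, next_id), max(x, next_id))
            dist[key] = _bag_from_matrix(d, bags[x], bags[next_id], mode)
        active.append(next_id)
        next_id += 1
    genes = nns.expression.gene_ids
    classes = [
        SystemClass(
            frozenset(members[c]),
            frozenset(genes[i] for i in bags[c]),
        )
        for c in sorted(active)
    ]
    ls = LearningSystem(
        classes=classes, gene_ids=list(genes), method_tag="MIHC",
        params={"stop_tau": stop_tau, "mode": mode},
    )
    return ls, Dendrogram(leaf_names=list(terms), merges=merges)
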
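"""Synthetic time-course data with planted co-expression modules.

The generator emulates the shape of a cell-cycle experiment: a handful of
gene modules, each following a periodic latent profile over one or a few
cycles, observed at equally spaced time points with Gaussian noise, plus
unannotated background genes of pure noise.  Module latents are drawn
from a harmonic family — module m oscillates at ``1 + m // 2`` cycles over
the series, modules sharing a frequency sit a quarter-period apart, and
every frequency gets a random global phase — so that distinct modules are
(near-)orthogonal while genes within a module stay strongly correlated.

A small ontology accompanies the expression data: one root, one mid-level
term per module and several leaf terms.  Each leaf is annotated with
genes of a single module, but a leaf's mid-level parent is assigned
round-robin across modules, mimicking the fact that DAG proximity does
not imply co-expression.  Ground-truth module assignments are returned
for both genes and leaf terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expression import TimeCourseMatrix
from .ontology import AnnotationMap, GoDag

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "perturb_labels"]


@dataclass
class SyntheticSpec:
    """Generator parameters.

    Defaults plant 4 modules of 3 terms x 8 genes each over 18 time
    points (7-minute sampling, as in a cell-cycle course) with profile
    noise of standard deviation 0.3 against unit signal amplitude, plus 30
    unannotated background genes.
    """

    n_modules: int = 4
    terms_per_module: int = 3
    genes_per_term: int = 8
    n_timepoints: int = 18
    within_noise_sd: float = 0.3
    background_genes: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_modules", "terms_per_module", "genes_per_term", "n_timepoints"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.within_noise_sd < 0:
            raise ValueError("within_noise_sd must be >= 0")
        if self.background_genes < 0:
            raise ValueError("background_genes must be >= 0")


@dataclass
class GroundTruth:
    """Planted module of every annotated gene and leaf term."""

    gene_module: dict[str, int] = field(default_factory=dict)
    term_module: dict[str, int] = field(default_factory=dict)


ROOT = "GO:0000001"


def _mid_id(i: int) -> str:
    return f"GO:{100 + i:07d}"


def _leaf_id(m: int, t: int) -> str:
    return f"GO:{1000 + 10 * m + t:07d}"


def generate(spec: SyntheticSpec) -> tuple[TimeCourseMatrix, GoDag, AnnotationMap, GroundTruth]:
    """Generate (expression, DAG, annotations, ground truth) for a spec.

    Deterministic given ``spec.seed``.  Module latents are
    ``sin(2*pi*k*j/n + phase)`` with ``k = 1 + m // 2`` cycles; background
    genes are standard-normal noise.
    """
    rng = np.random.default_rng(spec.seed)
    M, T, G, ntp = spec.n_modules, spec.terms_per_module, spec.genes_per_term, spec.n_timepoints
    j = np.arange(ntp)
    freq_phase: dict[int, float] = {}
    gene_ids: list[str] = []
    profiles: list[np.ndarray] = []
    truth = GroundTruth()
    for m in range(M):
        k = 1 + m // 2
        if k not in freq_phase:
            freq_phase[k] = rng.uniform(0, 2 * np.pi)
        phase = freq_phase[k] + (np.pi / 2 if m % 2 else 0.0)
        latent = np.sin(2 * np.pi * k * j / ntp + phase)
        for t in range(T):
            for i in range(G):
                gid = f"mod{m}_t{t}_g{i}"
                gene_ids.append(gid)
                profiles.append(latent + rng.normal(0.0, spec.within_noise_sd, ntp))
                truth.gene_module[gid] = m
    for b in range(spec.background_genes):
        gene_ids.append(f"bg_g{b}")
        profiles.append(rng.normal(0.0, 1.0, ntp))
    expr = TimeCourseMatrix(
        gene_ids=gene_ids,
        time_points=7.0 * j,
        values=np.array(profiles),
        missing_mask=np.zeros((len(gene_ids), ntp), dtype=bool),
    )
    edges = []
    for i in range(M):
        edges.append((_mid_id(i), ROOT))
    annot = AnnotationMap()
    for m in range(M):
        for t in range(T):
            leaf = _leaf_id(m, t)
            # round-robin parent: DAG neighbourhood cuts across modules
            edges.append((leaf, _mid_id((m + t) % M)))
            truth.term_module[leaf] = m
            for i in range(G):
                annot.add(f"mod{m}_t{t}_g{i}", leaf)
    dag = GoDag.from_edges(edges, namespace="biological_process")
    return expr, dag, annot, truth


def perturb_labels(annot: AnnotationMap, flip_rate: float, seed: int) -> AnnotationMap:
    """Reassign each (gene, term) pair to a random other term with
    probability ``flip_rate`` (a stress input for the non-noise selection)."""
    if not 0 <= flip_rate < 1:
        raise ValueError("flip_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    terms = annot.terms
    out = AnnotationMap()
    for gene, term in sorted(annot.pairs):
        if len(terms) > 1 and rng.random() < flip_rate:
            others = [t for t in terms if t != term]
            term = others[rng.integers(len(others))]
        out.add(gene, term)
    return out
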
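"""MiRNA similarity from GO annotations of target genes (miRSN-GOA).

Each miRNA is represented by the GO terms its target genes are annotated to,
each term carrying a weight measuring how surprising the annotation overlap
is. Term-term semantic similarity combines information content (IC) at the
lowest common ancestors (LCA) and highest common descendants (HCD):

    Sim(x, y) = min(1, (IC_L + IC_H) / (IC(x) + IC(y)))

with IC_L the maximum IC over the LCA set, IC_H the maximum IC over the HCD
set (0 when empty), and IC(x) = -ln(|G_x| / |G_root|) over descendant-closed
gene sets (true-path rule). Term weights come from the upper tail of the
hypergeometric distribution: w_x = -ln P(X >= k) for k of a miRNA's n targets
annotated to a term covering M of the N background genes; w_x = 0 when k = 0.

Two miRNAs' weighted term profiles are compared by a best-match, weighted,
normalized Euclidean aggregation, symmetrized by averaging both directions:

    s(q -> t) = sqrt( sum_x (Sim(x, B_t) * w_x)^2 / sum_x w_x^2 )
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence, Set

import numpy as np
from scipy.stats import hypergeom

from .core import AssociationTable, LabeledSimilarityMatrix, OntologyDAG

logger = logging.getLogger(__name__)


class AnnotatedGOGraph:
    """GO DAG with descendant-closed gene sets and per-term information content.

    ``annotations`` maps genes to terms (an :class:`AssociationTable` with
    genes on the left). Gene sets are closed downwards: a gene annotated to a
    term also counts for every ancestor of that term. Terms whose closed gene
    set is empty are pruned before IC computation. The background gene set
    G_root is the union of all annotated genes, so IC(root) = 0 for a
    single-root graph.
    """

    def __init__(self, dag: OntologyDAG, annotations: AssociationTable):
        direct: dict[str, set[str]] = {t: set() for t in dag.terms}
        for gene, term in annotations.pairs:
            if term in direct:
                direct[term].add(gene)
        closed: dict[str, set[str]] = {t: set(direct[t]) for t in dag.terms}
        # children before parents: propagate child gene sets upward
        for term in dag.topological_order():
            for parent in dag.parents(term):
                closed[parent] |= closed[term]
        background = set().union(*closed.values()) if closed else set()
        pruned = {t for t, genes in closed.items() if not genes}
        if pruned:
            logger.info("pruned %d GO terms with no annotated genes", len(pruned))
        self.dag = dag
        self.gene_sets: dict[str, set[str]] = {
            t: genes for t, genes in closed.items() if genes
        }
        self.root_genes: set[str] = background
        n_bg = len(background)
        self.ic: dict[str, float] = {
            t: -math.log(len(genes) / n_bg) for t, genes in self.gene_sets.items()
        }

    @property
    def terms(self) -> set[str]:
        """Terms surviving pruning (annotated to at least one gene)."""
        return set(self.gene_sets)

    def annotated_terms(self, genes: Set[str]) -> set[str]:
        """Terms whose closed gene set intersects ``genes``."""
        return {t for t, gs in self.gene_sets.items() if gs & genes}


def information_content(graph: AnnotatedGOGraph, term: str) -> float:
    """IC(x) = -ln(|G_x| / |G_root|); defined only for non-pruned terms."""
    if term not in graph.ic:
        raise KeyError(f"term {term!r} has no annotated genes (pruned)")
    return graph.ic[term]


def lca_hcd(graph: AnnotatedGOGraph, x: str, y: str) -> tuple[set[str], set[str]]:
    """Lowest common ancestors and highest common descendants of a term pair.

    Both are inclusive: a term is its own ancestor and descendant, so
    lca_hcd(x, x) = ({x}, {x}). The HCD set may be empty.
    """
    dag = graph.dag
    anc_x, anc_y = dag.ancestor_closure(x), dag.ancestor_closure(y)
    common_anc = anc_x & anc_y
    lca = {
        t for t in common_anc
        if not (dag.descendant_closure(t) - {t}) & common_anc
    }
    desc_x, desc_y = dag.descendant_closure(x), dag.descendant_closure(y)
    common_desc = desc_x & desc_y
    hcd = {
        t for t in common_desc
        if not (dag.ancestor_closure(t) - {t}) & common_desc
    }
    return lca, hcd


def go_term_similarity(graph: AnnotatedGOGraph, x: str, y: str) -> float:
    """Semantic similarity of two GO terms in [0, 1]."""
    ic_x = information_content(graph, x)
    ic_y = information_content(graph, y)
    lca, hcd = lca_hcd(graph, x, y)
    ic_l = max((graph.ic[t] for t in lca if t in graph.ic), default=0.0)
    ic_h = max((graph.ic[t] for t in hcd if t in graph.ic), default=0.0)
    denom = ic_x + ic_y
    if denom == 0.0:
        # both terms are roots carrying zero information
        return 1.0 if x == y else 0.0
    return min(1.0, (ic_l + ic_h) / denom)


def term_weight(N: int, M: int, n: int, k: int) -> float:
    """Hypergeometric surprise weight w = -ln P(X >= k); 0 when k = 0.

    N background genes, M of them annotated to the term, n miRNA targets,
    k targets annotated to the term.
    """
    if not (0 <= M <= N and 0 <= n <= N and 0 <= k <= min(n, M)):
        raise ValueError(f"impossible counts N={N}, M={M}, n={n}, k={k}")
    if k == 0:
        return 0.0
    tail = float(hypergeom.sf(k - 1, N, M, n))
    if tail <= 0.0:
        # beyond double precision: fall back to the log of the point mass at k
        return -float(hypergeom.logpmf(k, N, M, n))
    return -math.log(tail)


@dataclass(frozen=True)
class TermWeighting:
    """One miRNA's positively-weighted GO term profile."""

    mirna: str
    weights: Mapping[str, float]
    background_size: int
    target_count: int

    @property
    def terms(self) -> set[str]:
        return set(self.weights)


def build_term_weighting(
    graph: AnnotatedGOGraph, mirna: str, targets: Set[str]
) -> TermWeighting:
    """Weight every GO term overlapping the miRNA's in-background targets."""
    in_bg = targets & graph.root_genes
    if not in_bg:
        raise ValueError(f"miRNA {mirna!r} has no target with a GO annotation")
    N = len(graph.root_genes)
    n = len(in_bg)
    weights: dict[str, float] = {}
    for term in graph.annotated_terms(in_bg):
        M = len(graph.gene_sets[term])
        k = len(graph.gene_sets[term] & in_bg)
        w = term_weight(N, M, k=k, n=n)
        if w > 0.0:
            weights[term] = w
    return TermWeighting(
        mirna=mirna, weights=weights, background_size=N, target_count=n
    )


def _best_match(
    graph: AnnotatedGOGraph,
    term: str,
    others: Set[str],
    cache: dict[frozenset, float] | None,
) -> float:
    best = 0.0
    for other in others:
        key = frozenset((term, other)) if cache is not None else None
        if cache is not None and key in cache:
            s = cache[key]
        else:
            s = go_term_similarity(graph, term, other)
            if cache is not None:
                cache[key] = s
        if s > best:
            best = s
    return best


def mirgofs_similarity(
    graph: AnnotatedGOGraph,
    weights_q: TermWeighting,
    weights_t: TermWeighting,
    _cache: dict[frozenset, float] | None = None,
) -> float:
    """Symmetric similarity of two weighted GO term profiles, in [0, 1]."""
    if not weights_q.weights or not weights_t.weights:
        empty = weights_q if not weights_q.weights else weights_t
        raise ValueError(f"miRNA {empty.mirna!r} has an all-zero term weighting")

    def directed(a: TermWeighting, b: TermWeighting) -> float:
        num = 0.0
        den = 0.0
        for term, w in a.weights.items():
            s = _best_match(graph, term, b.terms, _cache)
            num += (s * w) ** 2
            den += w * w
        return math.sqrt(num / den)

    return (directed(weights_q, weights_t) + directed(weights_t, weights_q)) / 2.0


def build_mirsn_goa(
    targets: AssociationTable,
    dag: OntologyDAG,
    annotations: AssociationTable,
) -> LabeledSimilarityMatrix:
    """Build the GO-annotation miRNA similarity network.

    ``targets`` maps miRNAs to target genes; ``annotations`` maps genes to GO
    terms. MiRNAs whose targets all lack GO annotations, or whose term
    weights are all zero, are excluded (logged).
    """
    graph = AnnotatedGOGraph(dag, annotations)
    weightings: dict[str, TermWeighting] = {}
    excluded: list[str] = []
    for mirna in sorted(targets.mirnas):
        tg = targets.annotations_of(mirna)
        try:
            w = build_term_weighting(graph, mirna, tg)
        except ValueError:
            excluded.append(mirna)
            continue
        if not w.weights:
            excluded.append(mirna)
            continue
        weightings[mirna] = w
    if excluded:
        logger.info(
            "excluding %d miRNAs with no usable GO annotation: %s",
            len(excluded), excluded[:10],
        )
    mirnas = sorted(weightings)
    if not mirnas:
        raise ValueError("no miRNA has targets with usable GO annotations")
    n = len(mirnas)
    values = np.eye(n)
    cache: dict[frozenset, float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            s = mirgofs_similarity(
                graph, weightings[mirnas[i]], weightings[mirnas[j]], _cache=cache
            )
            values[i, j] = values[j, i] = s
    return LabeledSimilarityMatrix(mirnas, values)
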
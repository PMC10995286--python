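"""MiRNA similarity from PPI shortest paths between target genes (miRSN-PPI).

Two miRNAs are similar when their target genes sit close together on the
protein-protein interaction network: the score is the reciprocal of the mean
shortest-path hop distance over all reachable ordered target pairs, capped at
1 so all similarity networks share the [0, 1] scale. Unreachable pairs are
excluded from both numerator and denominator; if every reachable pair has
distance 0 (identical single targets) the similarity is 1 by convention, and
with no reachable pair at all it is 0.
"""

from __future__ import annotations

import logging
from typing import Iterable, Set

import networkx as nx
import numpy as np

from .core import AssociationTable, LabeledSimilarityMatrix

logger = logging.getLogger(__name__)


class PPINGraph:
    """Undirected, unweighted protein-protein interaction network.

    Self-loops are dropped and duplicate/reversed edges collapse.
    """

    def __init__(self, edges: Iterable[tuple[str, str]]):
        g = nx.Graph()
        for a, b in edges:
            if a == b:
                continue
            g.add_edge(a, b)
        self._g = g

    @classmethod
    def from_graph(cls, g: nx.Graph) -> "PPINGraph":
        return cls(g.edges)

    @property
    def proteins(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def interactions(self) -> set[frozenset]:
        return {frozenset(e) for e in self._g.edges}

    def __contains__(self, protein: str) -> bool:
        return protein in self._g

    def distances_from(self, source: str) -> dict[str, int]:
        """BFS hop distances from one protein to every reachable protein."""
        return nx.single_source_shortest_path_length(self._g, source)


def pairwise_distances(
    graph: PPINGraph,
    set_a: Set[str],
    set_b: Set[str],
    label_a: str = "A",
    label_b: str = "B",
) -> tuple[list[tuple[str, str, int]], int]:
    """Finite shortest-path distances for all ordered pairs (a in A, b in B).

    Returns the reachable pairs with their distances and the count of
    unreachable (omitted) pairs. Gene sets are first restricted to graph
    nodes; a set with no gene in the graph is an error naming its miRNA.
    """
    a_in = sorted(set_a & graph.proteins)
    b_in = sorted(set_b & graph.proteins)
    if not a_in:
        raise ValueError(f"no target gene of {label_a!r} is present in the PPIN")
    if not b_in:
        raise ValueError(f"no target gene of {label_b!r} is present in the PPIN")
    b_set = set(b_in)
    pairs: list[tuple[str, str, int]] = []
    skipped = 0
    for a in a_in:
        dist = graph.distances_from(a)
        for b in b_in:
            if b in dist:
                pairs.append((a, b, dist[b]))
            else:
                skipped += 1
    return pairs, skipped


def mirfunsim(
    graph: PPINGraph,
    targets_1: Set[str],
    targets_2: Set[str],
    label_1: str = "m1",
    label_2: str = "m2",
) -> float:
    """Reciprocal mean target-gene distance between two miRNAs, capped at 1."""
    pairs, _ = pairwise_distances(graph, targets_1, targets_2, label_1, label_2)
    if not pairs:
        return 0.0
    total = sum(d for _, _, d in pairs)
    if total == 0:
        return 1.0
    return min(1.0, len(pairs) / total)


def build_mirsn_ppi(
    targets: AssociationTable, graph: PPINGraph
) -> LabeledSimilarityMatrix:
    """Build the PPI-distance miRNA similarity network.

    MiRNAs whose targets all fall outside the PPIN are excluded (logged).
    The diagonal is fixed at 1.
    """
    usable: dict[str, set[str]] = {}
    excluded = []
    for mirna in sorted(targets.mirnas):
        in_graph = targets.annotations_of(mirna) & graph.proteins
        if in_graph:
            usable[mirna] = in_graph
        else:
            excluded.append(mirna)
    if excluded:
        logger.info(
            "excluding %d miRNAs with no target in the PPIN: %s",
            len(excluded), excluded[:10],
        )
    mirnas = sorted(usable)
    if not mirnas:
        raise ValueError("no miRNA has any target gene in the PPIN")
    n = len(mirnas)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = mirfunsim(
                graph, usable[mirnas[i]], usable[mirnas[j]],
                mirnas[i], mirnas[j],
            )
            values[i, j] = values[j, i] = s
    return LabeledSimilarityMatrix(mirnas, values)
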
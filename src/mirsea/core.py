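"""Shared domain types for the miRNA similarity-network pipeline.

The pipeline's in-memory currency is a small set of containers: a labelled
symmetric similarity matrix (the representation of every miRNA similarity
network and of the fused miRNA-miRNA association network), an ontology DAG
(MeSH-like disease hierarchies and GO graphs), a many-to-many association
table (miRNA-disease and miRNA-target links, gene-term annotations), a named
miRNA-set knowledge base, and one enrichment-result row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

#: Asymmetry below this is silently repaired by averaging; above it is an error.
SYMMETRY_TOL = 1e-9


class LabeledSimilarityMatrix:
    """Symmetric entity-by-entity similarity matrix with string labels.

    Values are dimensionless similarities, expected in [0, 1], with a unit
    diagonal (every entity is maximally similar to itself). The constructor
    validates squareness, finiteness, non-negativity and symmetry; asymmetry
    up to ``SYMMETRY_TOL`` is repaired by averaging with the transpose.
    """

    def __init__(self, ids: Sequence[str], values: np.ndarray):
        ids = list(ids)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids in similarity matrix")
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"matrix must be square, got shape {values.shape}")
        if values.shape[0] != len(ids):
            raise ValueError(
                f"{len(ids)} ids but matrix of shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("similarity matrix contains non-finite entries")
        if np.any(values < 0):
            raise ValueError("similarity matrix contains negative entries")
        asym = float(np.max(np.abs(values - values.T))) if len(ids) else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(
                f"matrix asymmetric: worst |S - S.T| = {asym:.3e}"
            )
        if asym > 0:
            logger.debug("symmetrizing matrix (worst asymmetry %.3e)", asym)
            values = (values + values.T) / 2.0
        if len(ids) and np.max(np.abs(np.diag(values) - 1.0)) > SYMMETRY_TOL:
            raise ValueError("similarity matrix diagonal must be 1")
        if len(ids):
            np.fill_diagonal(values, 1.0)
        self.ids: list[str] = ids
        self.values: np.ndarray = values
        self._index = {v: i for i, v in enumerate(ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, entity: str) -> bool:
        return entity in self._index

    def index(self, entity: str) -> int:
        try:
            return self._index[entity]
        except KeyError:
            raise KeyError(f"entity {entity!r} not in similarity matrix") from None

    def loc(self, a: str, b: str) -> float:
        """Similarity between two labelled entities."""
        return float(self.values[self.index(a), self.index(b)])

    def submatrix(self, ids: Sequence[str]) -> "LabeledSimilarityMatrix":
        idx = [self.index(i) for i in ids]
        return LabeledSimilarityMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def equals(self, other: "LabeledSimilarityMatrix", atol: float = 0.0) -> bool:
        return self.ids == other.ids and bool(
            np.allclose(self.values, other.values, rtol=0.0, atol=atol)
        )

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"LabeledSimilarityMatrix({len(self.ids)} entities)"


class OntologyDAG:
    """Directed acyclic graph of ontology terms with child-to-parent edges.

    Roots are the terms without parents. Ancestor/descendant queries are
    inclusive of the query term itself, matching the closure semantics used
    by semantic-similarity measures.
    """

    def __init__(self, terms: Iterable[str], edges: Iterable[tuple[str, str]]):
        g = nx.DiGraph()
        g.add_nodes_from(terms)
        for child, parent in edges:
            if child == parent:
                raise ValueError(f"term {child!r} is its own parent")
            g.add_edge(child, parent)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle is not None:
            path = " -> ".join(str(e[0]) for e in cycle)
            raise ValueError(f"ontology contains a cycle: {path}")
        self._g = g

    @property
    def terms(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self._g.edges)

    @property
    def roots(self) -> set[str]:
        return {n for n in self._g.nodes if self._g.out_degree(n) == 0}

    def __contains__(self, term: str) -> bool:
        return term in self._g

    def parents(self, term: str) -> set[str]:
        return set(self._g.successors(term))

    def children(self, term: str) -> set[str]:
        return set(self._g.predecessors(term))

    def ancestor_closure(self, term: str) -> set[str]:
        """The term plus every ancestor reachable over child->parent edges."""
        if term not in self._g:
            raise KeyError(f"term {term!r} not in ontology")
        return {term} | nx.descendants(self._g, term)

    def descendant_closure(self, term: str) -> set[str]:
        """The term plus every descendant."""
        if term not in self._g:
            raise KeyError(f"term {term!r} not in ontology")
        return {term} | nx.ancestors(self._g, term)

    def topological_order(self) -> list[str]:
        """Children before parents."""
        return list(nx.topological_sort(self._g))

    def __len__(self) -> int:
        return self._g.number_of_nodes()


class AssociationTable:
    """Deduplicated many-to-many map between miRNA IDs and annotation IDs.

    Also reused for gene-to-GO-term annotation tables; the two sides are just
    called "left" (miRNA or gene) and "right" (annotation term). Lookups of
    absent keys yield the empty set.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        self.pairs: set[tuple[str, str]] = set(pairs)
        self._by_left: dict[str, set[str]] = {}
        self._by_right: dict[str, set[str]] = {}
        for left, right in self.pairs:
            self._by_left.setdefault(left, set()).add(right)
            self._by_right.setdefault(right, set()).add(left)

    @property
    def mirnas(self) -> set[str]:
        return set(self._by_left)

    @property
    def annotations(self) -> set[str]:
        return set(self._by_right)

    def annotations_of(self, mirna: str) -> set[str]:
        return set(self._by_left.get(mirna, ()))

    def mirnas_of(self, annotation: str) -> set[str]:
        return set(self._by_right.get(annotation, ()))

    def restrict_annotations(self, keep: set[str]) -> "AssociationTable":
        """Drop pairs whose annotation is outside ``keep``."""
        return AssociationTable((l, r) for l, r in self.pairs if r in keep)

    def __len__(self) -> int:
        return len(self.pairs)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AssociationTable) and self.pairs == other.pairs

    def __hash__(self):  # pragma: no cover
        return hash(frozenset(self.pairs))


@dataclass(frozen=True)
class MiRNASet:
    name: str
    category: str
    members: tuple[str, ...]


class MiRNASetKB:
    """Named miRNA sets with category labels (disease sets, function sets).

    The universe is the union of all members; it plays the role of the
    reference miRNA collection (size N) in the hypergeometric test.
    """

    def __init__(self, sets: Iterable[tuple[str, str, Sequence[str]]]):
        parsed: list[MiRNASet] = []
        seen_names: set[str] = set()
        for name, category, members in sets:
            dedup = tuple(dict.fromkeys(members))
            if not dedup:
                raise ValueError(f"miRNA set {name!r} has no members")
            if name in seen_names:
                raise ValueError(f"duplicate set name {name!r}")
            seen_names.add(name)
            parsed.append(MiRNASet(name, category, dedup))
        if not parsed:
            raise ValueError("knowledge base contains no sets")
        self.sets: list[MiRNASet] = parsed
        self.universe: set[str] = set().union(*(s.members for s in parsed))

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


@dataclass(frozen=True)
class EnrichmentRow:
    """One knowledge-base set's over-representation result."""

    set_name: str
    category: str
    set_size: int
    overlap: int
    p_value: float
    fdr: float
    significant: bool
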
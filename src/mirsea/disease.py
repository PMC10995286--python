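"""Wang-style semantic similarity between diseases on a MeSH-like DAG.

Each disease ``d`` is viewed through the sub-DAG of its ancestor closure
``T_d``. Every term ``t`` in the closure contributes semantically to ``d``:
the disease itself contributes 1, and each step up the hierarchy decays the
contribution by a factor ``decay`` (Delta, default 0.5). Where multiple
upward paths exist the maximum contribution — equivalently the shortest hop
path — is taken. The semantic value DV(d) is the sum of all contributions,
and two diseases are compared by how much of their semantic value lives on
shared ancestors:

    S(di, dj) = sum_{t in T_i ∩ T_j} (D_i(t) + D_j(t)) / (DV_i + DV_j)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import LabeledSimilarityMatrix, OntologyDAG


@dataclass(frozen=True)
class DiseaseDAGView:
    """A disease's ancestor closure with per-term semantic contributions."""

    disease: str
    decay: float
    ancestor_set: frozenset[str]
    contribution: Mapping[str, float]

    @property
    def semantic_value(self) -> float:
        """DV(d): the sum of contributions over the ancestor closure."""
        return float(sum(self.contribution.values()))


def build_dag_view(
    ontology: OntologyDAG, disease: str, decay: float = 0.5
) -> DiseaseDAGView:
    """Compute per-ancestor semantic contributions for one disease.

    Contributions are computed bottom-up: D_d(d) = 1 and, for an ancestor t,
    D_d(t) = max over children t' of t inside the closure of decay * D_d(t').
    Children outside the closure carry no defined contribution and cannot
    participate. The result equals decay ** (minimum hop count from d to t).
    """
    if disease not in ontology:
        raise KeyError(f"disease {disease!r} not found in ontology")
    if not (0.0 < decay < 1.0):
        raise ValueError(f"decay must be in (0, 1), got {decay}")
    closure = ontology.ancestor_closure(disease)
    # children-before-parents order restricted to the closure
    order = [t for t in ontology.topological_order() if t in closure]
    contribution: dict[str, float] = {}
    for t in order:
        if t == disease:
            contribution[t] = 1.0
        else:
            in_closure = [c for c in ontology.children(t) if c in contribution]
            # every proper ancestor of d has >=1 child on a path back to d
            contribution[t] = decay * max(contribution[c] for c in in_closure)
    return DiseaseDAGView(
        disease=disease,
        decay=decay,
        ancestor_set=frozenset(closure),
        contribution=contribution,
    )


def disease_similarity(view_i: DiseaseDAGView, view_j: DiseaseDAGView) -> float:
    """Semantic similarity between two diseases from their DAG views.

    Both views must come from the same ontology with the same decay.
    """
    if view_i.decay != view_j.decay:
        raise ValueError("views built with different decay factors")
    shared = view_i.ancestor_set & view_j.ancestor_set
    if not shared:
        return 0.0
    numerator = sum(
        view_i.contribution[t] + view_j.contribution[t] for t in shared
    )
    return numerator / (view_i.semantic_value + view_j.semantic_value)


def disease_similarity_matrix(
    ontology: OntologyDAG, diseases: Sequence[str], decay: float = 0.5
) -> LabeledSimilarityMatrix:
    """Pairwise disease similarity; each disease's DAG is traversed once."""
    diseases = list(dict.fromkeys(diseases))
    views = {d: build_dag_view(ontology, d, decay) for d in diseases}
    n = len(diseases)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = disease_similarity(views[diseases[i]], views[diseases[j]])
            values[i, j] = values[j, i] = s
    return LabeledSimilarityMatrix(diseases, values)
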
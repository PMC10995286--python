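"""MiRNA functional similarity from shared disease associations (miRSN-DA).

Two miRNAs are functionally similar to the extent that the diseases they are
associated with are semantically similar. With D1, D2 the disease sets of the
two miRNAs (sizes m, n) and S a disease-disease semantic similarity matrix:

    sim(m1, m2) = ( sum_{d in D1} S(d, D2) + sum_{d in D2} S(d, D1) ) / (m + n)

where S(d, D) is the best match of d against the set D (the maximum pairwise
similarity). The score is symmetric by construction and lies in [0, 1] when
S does.
"""

from __future__ import annotations

import logging
from typing import Iterable, Set

import numpy as np

from .core import AssociationTable, LabeledSimilarityMatrix, OntologyDAG
from .disease import disease_similarity_matrix

logger = logging.getLogger(__name__)


def disease_to_set_similarity(
    d: str, disease_set: Set[str], sim: LabeledSimilarityMatrix
) -> float:
    """Best-match similarity between disease ``d`` and a non-empty disease set."""
    if not disease_set:
        raise ValueError("disease set is empty; best-match similarity undefined")
    return max(sim.loc(d, di) for di in disease_set)


def misim(
    m1: str,
    m2: str,
    assoc: AssociationTable,
    sim: LabeledSimilarityMatrix,
) -> float:
    """Functional similarity of two miRNAs from their disease associations."""
    d1 = assoc.annotations_of(m1)
    d2 = assoc.annotations_of(m2)
    if not d1 or not d2:
        missing = m1 if not d1 else m2
        raise ValueError(f"miRNA {missing!r} has no disease associations")
    total = sum(disease_to_set_similarity(d, d2, sim) for d in d1)
    total += sum(disease_to_set_similarity(d, d1, sim) for d in d2)
    return total / (len(d1) + len(d2))


def build_mirsn_da(
    assoc: AssociationTable,
    ontology: OntologyDAG,
    decay: float = 0.5,
) -> LabeledSimilarityMatrix:
    """Build the disease-association miRNA similarity network.

    Disease associations whose disease is absent from the ontology are
    dropped (logged); a miRNA left without any disease is excluded from the
    network, since the best-match similarity is undefined on empty sets.
    """
    known = assoc.annotations & ontology.terms
    dropped = assoc.annotations - known
    if dropped:
        logger.info(
            "dropping %d diseases absent from the ontology: %s",
            len(dropped), sorted(dropped)[:10],
        )
    usable = assoc.restrict_annotations(known)
    mirnas = sorted(usable.mirnas)
    excluded = sorted(assoc.mirnas - usable.mirnas)
    if excluded:
        logger.info("excluding %d miRNAs with no in-ontology disease", len(excluded))
    if not mirnas:
        raise ValueError("no miRNA has any disease present in the ontology")

    diseases = sorted(usable.annotations)
    dsim = disease_similarity_matrix(ontology, diseases, decay)

    n = len(mirnas)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = misim(mirnas[i], mirnas[j], usable, dsim)
            values[i, j] = values[j, i] = s
    return LabeledSimilarityMatrix(mirnas, values)
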
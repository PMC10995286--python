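"""Seeded generators for every input the pipeline consumes.

All generators are pure functions of their parameters plus a single integer
seed. Each generator draws from its own named pseudo-random stream derived
from that seed, so adding a generator never perturbs another's draws.

The planted scenario is the test harness for the end-to-end claim the
pipeline makes: a cohesive miRNA module that is strongly similar in two of
the three networks should be recoverable by random-walk expansion from half
its members, and its knowledge-base set should dominate the enrichment
ranking against random decoy sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    AssociationTable,
    LabeledSimilarityMatrix,
    MiRNASetKB,
    OntologyDAG,
)
from .mirfunsim import PPINGraph

_STREAMS = {
    "ontology": 0,
    "associations": 1,
    "ppin": 2,
    "go_annotations": 3,
    "planted": 4,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


def gen_ontology(
    n_terms: int, max_parents: int = 2, seed: int = 0, prefix: str = "t"
) -> OntologyDAG:
    """Random single-root DAG built by topological insertion.

    Term i > 0 picks 1..max_parents parents among terms 0..i-1, so the graph
    is acyclic by construction with term 0 the unique root.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = _rng(seed, "ontology")
    terms = [f"{prefix}{i:03d}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        k = int(rng.integers(1, min(max_parents, i) + 1))
        parents = rng.choice(i, size=k, replace=False)
        for p in sorted(int(x) for x in parents):
            edges.append((terms[i], terms[p]))
    return OntologyDAG(terms, edges)


def gen_associations(
    mirnas: Sequence[str],
    annotations: Sequence[str],
    density: float = 0.2,
    seed: int = 0,
) -> AssociationTable:
    """Bernoulli miRNA-annotation pairs; every miRNA gets >= 1 annotation."""
    if not (0.0 < density <= 1.0):
        raise ValueError("density must be in (0, 1]")
    rng = _rng(seed, "associations")
    pairs = []
    for m in mirnas:
        hits = rng.random(len(annotations)) < density
        chosen = [a for a, h in zip(annotations, hits) if h]
        if not chosen:
            chosen = [annotations[int(rng.integers(len(annotations)))]]
        pairs.extend((m, a) for a in chosen)
    return AssociationTable(pairs)


def gen_ppin(
    n_genes: int, edge_prob: float = 0.1, seed: int = 0, prefix: str = "g"
) -> PPINGraph:
    """Erdos-Renyi interaction graph; only the largest component is kept."""
    if not (0.0 < edge_prob <= 1.0):
        raise ValueError("edge_prob must be in (0, 1]")
    rng = _rng(seed, "ppin")
    genes = [f"{prefix}{i:03d}" for i in range(n_genes)]
    edges = []
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < edge_prob:
                edges.append((genes[i], genes[j]))
    graph = PPINGraph(edges)
    import networkx as nx

    g = nx.Graph(list(tuple(e) for e in graph.interactions))
    if g.number_of_nodes() == 0:
        # degenerate draw: fall back to a path so the graph is non-empty
        g = nx.path_graph(genes[: max(2, n_genes)])
        g = nx.relabel_nodes(g, dict(enumerate(genes)))
    largest = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)[0]))
    return PPINGraph(g.subgraph(largest).edges)


def gen_go_annotations(
    dag: OntologyDAG,
    genes: Sequence[str],
    seed: int = 0,
    terms_per_gene: tuple[int, int] = (1, 3),
) -> AssociationTable:
    """Random gene-to-term annotations, closed upward (true-path rule)."""
    rng = _rng(seed, "go_annotations")
    terms = sorted(dag.terms)
    lo, hi = terms_per_gene
    pairs = []
    for gene in genes:
        k = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(terms), size=min(k, len(terms)), replace=False)
        closure: set[str] = set()
        for idx in chosen:
            closure |= dag.ancestor_closure(terms[int(idx)])
        pairs.extend((gene, t) for t in sorted(closure))
    return AssociationTable(pairs)


@dataclass(frozen=True)
class PlantedConfig:
    """Effect sizes of the planted-module scenario.

    Within-module similarities are drawn from [within_low, within_high] in
    the two carrying networks; all other pairs (and the whole third network)
    draw from [background_low, background_high]. The gap is wide enough that
    the fused within-module edges survive the default similarity threshold
    while background edges do not.
    """

    within_low: float = 0.8
    within_high: float = 0.95
    background_low: float = 0.05
    background_high: float = 0.3
    n_decoys: int = 24
    decoy_size: int = 20


@dataclass(frozen=True)
class PlantedScenario:
    """Three similarity networks, a knowledge base, a seed list, and truth."""

    mirsn_da: LabeledSimilarityMatrix
    mirsn_goa: LabeledSimilarityMatrix
    mirsn_ppi: LabeledSimilarityMatrix
    kb: MiRNASetKB
    input_list: tuple[str, ...]
    module: tuple[str, ...]
    planted_set_name: str = "planted_module"

    @property
    def networks(self) -> tuple[LabeledSimilarityMatrix, ...]:
        return (self.mirsn_da, self.mirsn_goa, self.mirsn_ppi)


def _random_similarity(
    rng: np.random.Generator,
    ids: Sequence[str],
    lo: float,
    hi: float,
    module_idx: Sequence[int] | None = None,
    module_lo: float = 0.0,
    module_hi: float = 0.0,
) -> LabeledSimilarityMatrix:
    n = len(ids)
    upper = rng.uniform(lo, hi, size=(n, n))
    values = np.triu(upper, 1)
    values = values + values.T
    if module_idx is not None:
        for ii, a in enumerate(module_idx):
            for b in module_idx[ii + 1:]:
                v = rng.uniform(module_lo, module_hi)
                values[a, b] = values[b, a] = v
    np.fill_diagonal(values, 1.0)
    return LabeledSimilarityMatrix(list(ids), values)


def gen_planted_scenario(
    n_mirnas: int = 60,
    module_size: int = 20,
    seed: int = 7,
    config: PlantedConfig | None = None,
) -> PlantedScenario:
    """Generate the planted-module end-to-end scenario.

    One module of miRNAs is given high within-module similarity in the
    disease-association and GO-annotation networks and background-level
    similarity in the PPI network. The knowledge base holds the module as a
    set plus random decoy sets covering every miRNA; the input list is half
    the module.
    """
    if not (0 < module_size < n_mirnas):
        raise ValueError("module_size must be in (0, n_mirnas)")
    cfg = config or PlantedConfig()
    rng = _rng(seed, "planted")
    ids = [f"mir-{i:03d}" for i in range(n_mirnas)]
    module_idx = sorted(int(i) for i in rng.choice(n_mirnas, module_size, replace=False))
    module = tuple(ids[i] for i in module_idx)

    da = _random_similarity(
        rng, ids, cfg.background_low, cfg.background_high,
        module_idx, cfg.within_low, cfg.within_high,
    )
    goa = _random_similarity(
        rng, ids, cfg.background_low, cfg.background_high,
        module_idx, cfg.within_low, cfg.within_high,
    )
    ppi = _random_similarity(rng, ids, cfg.background_low, cfg.background_high)

    sets: list[tuple[str, str, list[str]]] = [
        ("planted_module", "Disease", list(module))
    ]
    covered = set(module)
    decoys = []
    for k in range(cfg.n_decoys):
        members = sorted(
            ids[int(i)]
            for i in rng.choice(n_mirnas, cfg.decoy_size, replace=False)
        )
        decoys.append(members)
        covered.update(members)
    # guarantee universe coverage: spread uncovered ids over the decoys
    for pos, missing in enumerate(sorted(set(ids) - covered)):
        decoys[pos % len(decoys)].append(missing)
    for k, members in enumerate(decoys):
        sets.append((f"decoy_{k:02d}", "Function", members))
    kb = MiRNASetKB(sets)

    half = module_size // 2
    input_list = tuple(ids[i] for i in module_idx[:half])
    return PlantedScenario(
        mirsn_da=da,
        mirsn_goa=goa,
        mirsn_ppi=ppi,
        kb=kb,
        input_list=input_list,
        module=module,
    )
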
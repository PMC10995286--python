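"""Random walk with restart on the fused miRNA network, and list expansion.

The fused similarity matrix is first sparsified: off-diagonal entries below
the similarity coefficient tau are deleted (entries equal to tau are kept)
and the diagonal is zeroed, leaving a weighted adjacency whose weights are
the surviving similarities. Columns are normalized to give the transition
matrix W, and the walk iterates

    r <- c * W @ r + (1 - c) * e

from r0 = e, with e uniform over the seed nodes present in the network. For
c < 1 the map is a contraction, so convergence is guaranteed. Non-seed nodes
with positive steady-state probability are ranked and the top fraction
(default one half) joins the user's list to form the expanded miRNA list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import LabeledSimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RWRConfig:
    """Walk parameters.

    c: weight on the walk term of the update (restart mass is 1 - c).
    similarity_threshold: tau, the edge-retention cutoff on the fused network.
    keep_fraction: share of ranked positive non-seed nodes added to the list.
    tol: L1 convergence tolerance; max_iter: iteration cap.
    """

    c: float = 0.85
    similarity_threshold: float = 0.6
    keep_fraction: float = 0.5
    tol: float = 1e-10
    max_iter: int = 10000

    def __post_init__(self):
        if not (0.0 < self.c < 1.0):
            raise ValueError(f"c must be in (0, 1), got {self.c}")
        if not (0.0 <= self.similarity_threshold <= 1.0):
            raise ValueError(
                f"similarity_threshold must be in [0, 1], got {self.similarity_threshold}"
            )
        if not (0.0 < self.keep_fraction <= 1.0):
            raise ValueError(
                f"keep_fraction must be in (0, 1], got {self.keep_fraction}"
            )
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be positive and max_iter >= 1")


@dataclass(frozen=True)
class ExpansionResult:
    """Outcome of one expansion run."""

    scores: Mapping[str, float]
    seeds: tuple[str, ...]
    added: tuple[str, ...]
    expanded_list: tuple[str, ...]
    iterations: int = 0


def threshold_network(
    matrix: LabeledSimilarityMatrix, tau: float
) -> tuple[list[str], np.ndarray]:
    """Weighted adjacency after the similarity-coefficient cutoff.

    Entries >= tau keep their similarity as edge weight; the diagonal is
    zeroed (no self-loops in the walk).
    """
    if not (0.0 <= tau <= 1.0):
        raise ValueError(f"tau must be in [0, 1], got {tau}")
    adj = matrix.values.copy()
    adj[adj < tau] = 0.0
    np.fill_diagonal(adj, 0.0)
    return list(matrix.ids), adj


def transition_matrix(adj: np.ndarray) -> np.ndarray:
    """Column-normalize non-negative weights; dangling columns stay all-zero."""
    if np.any(adj < 0):
        raise ValueError("adjacency weights must be non-negative")
    col_sums = adj.sum(axis=0)
    w = np.divide(
        adj, col_sums[np.newaxis, :],
        out=np.zeros_like(adj), where=col_sums > 0,
    )
    return w


def rwr(
    w: np.ndarray,
    ids: Sequence[str],
    seeds: Sequence[str],
    cfg: RWRConfig | None = None,
) -> tuple[dict[str, float], int]:
    """Iterate the walk to its steady state; returns (scores, iterations)."""
    cfg = cfg or RWRConfig()
    present = [s for s in seeds if s in set(ids)]
    missing = sorted(set(seeds) - set(ids))
    if not present:
        raise ValueError(f"no seed present in the network; missing: {missing}")
    index = {v: i for i, v in enumerate(ids)}
    e = np.zeros(len(ids))
    e[[index[s] for s in present]] = 1.0 / len(present)
    r = e.copy()
    for iteration in range(1, cfg.max_iter + 1):
        r_next = cfg.c * (w @ r) + (1.0 - cfg.c) * e
        residual = float(np.abs(r_next - r).sum())
        r = r_next
        if residual < cfg.tol:
            logger.info("random walk converged in %d iterations", iteration)
            return {mid: float(r[i]) for mid, i in index.items()}, iteration
    raise RuntimeError(
        f"random walk did not converge in {cfg.max_iter} iterations "
        f"(residual {residual:.3e})"
    )


def expand_list(
    scores: Mapping[str, float],
    seeds: Sequence[str],
    input_list: Sequence[str],
    keep_fraction: float = 0.5,
    iterations: int = 0,
) -> ExpansionResult:
    """Select top-ranked positive non-seed nodes and merge with the input list.

    Candidates are ranked by score descending, ties broken by lexicographic
    miRNA ID; floor(keep_fraction * n_candidates) are kept. Input miRNAs
    absent from the network pass through to the expanded list untouched.
    """
    seed_set = set(seeds)
    candidates = [
        m for m, s in scores.items() if s > 0.0 and m not in seed_set
    ]
    candidates.sort(key=lambda m: (-scores[m], m))
    n_keep = math.floor(keep_fraction * len(candidates))
    added = tuple(candidates[:n_keep])
    expanded = list(dict.fromkeys(input_list))
    for m in added:
        if m not in set(expanded):
            expanded.append(m)
    return ExpansionResult(
        scores=dict(scores),
        seeds=tuple(sorted(seed_set)),
        added=added,
        expanded_list=tuple(expanded),
        iterations=iterations,
    )


def expand(
    network: LabeledSimilarityMatrix,
    input_list: Sequence[str],
    cfg: RWRConfig | None = None,
) -> ExpansionResult:
    """Full chain: threshold, normalize, walk, select, merge."""
    cfg = cfg or RWRConfig()
    ids, adj = threshold_network(network, cfg.similarity_threshold)
    w = transition_matrix(adj)
    input_list = list(dict.fromkeys(input_list))
    seeds = [m for m in input_list if m in network]
    scores, iterations = rwr(w, ids, seeds, cfg)
    return expand_list(
        scores, seeds, input_list, cfg.keep_fraction, iterations=iterations
    )
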
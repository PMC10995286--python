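"""Fusion of miRNA similarity networks into one association network.

Networks over partially overlapping miRNA sets are combined on the union of
their ids. Each unordered pair's fused value is the mean of that pair's
similarity over the networks that contain BOTH miRNAs; a pair covered by a
single network keeps that network's value, and a pair covered by none (the
two miRNAs known only to different networks) gets 0 — no evidence, no edge.
The mean is taken simultaneously over all covering networks, which is
order-free, rather than by sequential pairwise averaging, which is not.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import LabeledSimilarityMatrix


def fuse(
    networks: Sequence[LabeledSimilarityMatrix], mode: str = "mean"
) -> LabeledSimilarityMatrix:
    """Fuse two or more similarity networks by per-pair averaging."""
    if mode != "mean":
        raise ValueError(f"unknown fusion mode {mode!r}")
    if len(networks) < 2:
        raise ValueError("fusion requires at least 2 networks")
    ids = sorted(set().union(*(set(n.ids) for n in networks)))
    size = len(ids)
    total = np.zeros((size, size))
    count = np.zeros((size, size))
    index = {v: i for i, v in enumerate(ids)}
    for net in networks:
        pos = np.array([index[i] for i in net.ids])
        total[np.ix_(pos, pos)] += net.values
        count[np.ix_(pos, pos)] += 1
    values = np.divide(total, count, out=np.zeros_like(total), where=count > 0)
    np.fill_diagonal(values, 1.0)
    return LabeledSimilarityMatrix(ids, values)


def fusion_report(networks: Sequence[LabeledSimilarityMatrix]) -> dict:
    """Coverage summary: id intersection/union and pair-coverage histogram."""
    id_sets = [set(n.ids) for n in networks]
    union = sorted(set().union(*id_sets))
    intersection = sorted(set.intersection(*id_sets))
    histogram: dict[int, int] = {}
    for i, a in enumerate(union):
        for b in union[i + 1:]:
            k = sum(1 for s in id_sets if a in s and b in s)
            histogram[k] = histogram.get(k, 0) + 1
    return {
        "n_networks": len(networks),
        "network_sizes": [len(s) for s in id_sets],
        "n_union": len(union),
        "n_intersection": len(intersection),
        "pair_coverage_histogram": {str(k): v for k, v in sorted(histogram.items())},
    }
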
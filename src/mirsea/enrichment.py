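"""Over-representation analysis of a miRNA list against a set knowledge base.

For an input list of n miRNAs drawn from a reference collection of N, and a
knowledge-base set of M miRNAs of which m overlap the list, the enrichment
p-value is the inclusive upper tail of the hypergeometric distribution:

    p = sum_{i=m}^{min(n, M)} C(M, i) C(N-M, n-i) / C(N, n)

P-values across all sets are corrected with the Benjamini-Hochberg step-up
(FDR); sets with FDR < 0.05 are flagged significant. The hit rate of a list
against a set is 100 * overlap / set size, rounded half-up to 2 decimals.
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core import EnrichmentRow, MiRNASetKB

logger = logging.getLogger(__name__)

FDR_THRESHOLD = 0.05


def hypergeom_pvalue(n: int, N: int, M: int, m: int) -> float:
    """Inclusive upper-tail hypergeometric p-value of an overlap of m."""
    if not (0 <= M <= N and 0 <= n <= N and 0 <= m <= min(n, M)):
        raise ValueError(f"impossible counts n={n}, N={N}, M={M}, m={m}")
    return float(hypergeom.sf(m - 1, N, M, n))


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    if len(pvalues) == 0:
        return []
    if any(not (0.0 < p <= 1.0) for p in pvalues):
        raise ValueError("p-values must lie in (0, 1]")
    return list(multipletests(list(pvalues), method="fdr_bh")[1])


def enrich(
    input_list: Sequence[str],
    kb: MiRNASetKB,
    fdr_threshold: float = FDR_THRESHOLD,
) -> list[EnrichmentRow]:
    """Test every knowledge-base set for over-representation in the list.

    The universe is the knowledge base's member union; input miRNAs outside
    it are dropped from n (logged). Rows come back sorted by p-value
    ascending, ties by set name.
    """
    deduped = list(dict.fromkeys(input_list))
    if len(deduped) != len(input_list):
        logger.info("input list: dropped %d duplicates", len(input_list) - len(deduped))
    in_universe = [m for m in deduped if m in kb.universe]
    outside = len(deduped) - len(in_universe)
    if outside:
        logger.info("input list: %d miRNAs outside the knowledge-base universe", outside)
    n = len(in_universe)
    if n == 0:
        raise ValueError("no input miRNA in knowledge-base universe")
    N = len(kb.universe)
    input_set = set(in_universe)
    overlaps = []
    pvals = []
    for s in kb.sets:
        m = len(input_set & set(s.members))
        overlaps.append(m)
        pvals.append(hypergeom_pvalue(n, N, len(s.members), m))
    fdrs = bh_fdr(pvals)
    rows = [
        EnrichmentRow(
            set_name=s.name,
            category=s.category,
            set_size=len(s.members),
            overlap=m,
            p_value=p,
            fdr=q,
            significant=bool(q < fdr_threshold),
        )
        for s, m, p, q in zip(kb.sets, overlaps, pvals, fdrs)
    ]
    rows.sort(key=lambda r: (r.p_value, r.set_name))
    return rows


def hit_rate(overlap: int, set_size: int) -> float:
    """Percent of a knowledge-base set covered by a list, half-up to 2 dp."""
    if set_size <= 0:
        raise ValueError("set_size must be positive")
    if not (0 <= overlap <= set_size):
        raise ValueError(f"overlap {overlap} outside [0, {set_size}]")
    pct = Decimal(100 * overlap) / Decimal(set_size)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
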
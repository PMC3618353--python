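"""McDonald–Kreitman tests and neutrality indices.

The MK test contrasts the nonsynonymous/synonymous composition of
polymorphism (Pn, Ps) with that of fixed differences (Dn, Ds) in a 2x2
Fisher exact test.  The neutrality index NI = (Pn/Ps)/(Dn/Ds) summarises the
direction of departure (>1: excess polymorphism, as expected under balancing
or weakly deleterious variation; <1: excess divergence, as under recurrent
positive selection).  Across a gene set NI is combined with the
ratio-of-averages weighting

    NI_w = sum_i[ Ds_i Pn_i / (Ps_i + Ds_i) ] / sum_i[ Ps_i Dn_i / (Ps_i + Ds_i) ]

which avoids the bias of averaging per-gene ratios with small counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import hypergeom

from .codon_counts import MKCounts
from .exceptions import UndefinedStatisticError


def fisher_exact_two_tailed(a: int, b: int, c: int, d: int, method: str = "point") -> float:
    """Two-tailed Fisher exact p for the table [[a, b], [c, d]].

    ``method='point'`` (default) sums the hypergeometric probabilities of all
    tables with the observed margins whose probability does not exceed the
    observed table's (the point-probability rule used by R and most
    population-genetics software).  ``method='double'`` doubles the smaller
    one-sided tail instead, capped at 1.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("cell counts must be nonnegative integers")
    M = a + b + c + d
    row1 = a + b
    col1 = a + c
    if M == 0 or row1 == 0 or row1 == M or col1 == 0 or col1 == M:
        return 1.0
    lo = max(0, row1 + col1 - M)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, M, col1, row1)
    p_obs = pmf[support == a][0]
    if method == "point":
        # relative tolerance guards against ties lost to rounding
        p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    elif method == "double":
        lower = float(pmf[support <= a].sum())
        upper = float(pmf[support >= a].sum())
        p = 2.0 * min(lower, upper)
    else:
        raise ValueError(f"unknown method {method!r}")
    return min(1.0, p)


@dataclass
class MkResult:
    gene_id: str
    p_value: float
    p_adjusted: float
    NI: Optional[float]
    direction: Optional[str]  # excess_polymorphism | excess_divergence | none
    counts: Optional[MKCounts] = None


def neutrality_index(counts: MKCounts) -> float:
    """NI = (Pn/Ps)/(Dn/Ds) = (Pn*Ds)/(Ps*Dn)."""
    if counts.Ps * counts.Dn == 0:
        raise UndefinedStatisticError(
            f"{counts.gene_id}: NI undefined (Ps*Dn = 0)"
        )
    return (counts.Pn * counts.Ds) / (counts.Ps * counts.Dn)


def mk_test(counts: MKCounts, m_tests: int = 1) -> MkResult:
    """Fisher exact MK test with Bonferroni adjustment over ``m_tests``."""
    p = fisher_exact_two_tailed(counts.Pn, counts.Ps, counts.Dn, counts.Ds)
    p_adj = min(1.0, p * m_tests)
    lhs = counts.Pn * counts.Ds  # Pn/Ps > Dn/Ds  <=>  Pn*Ds > Dn*Ps
    rhs = counts.Dn * counts.Ps
    if counts.Ps == 0 and counts.Ds == 0:
        direction = None
    elif lhs > rhs:
        direction = "excess_polymorphism"
    elif lhs < rhs:
        direction = "excess_divergence"
    else:
        direction = "none"
    try:
        ni = neutrality_index(counts)
    except UndefinedStatisticError:
        ni = None
    return MkResult(counts.gene_id, p, p_adj, ni, direction, counts)


def weighted_neutrality_index(gene_counts: Sequence[MKCounts]) -> float:
    """Ratio-of-weighted-sums NI over a gene set (no internal rounding)."""
    if not gene_counts:
        raise UndefinedStatisticError("empty gene set")
    num = sum(
        c.Ds * c.Pn / (c.Ps + c.Ds) for c in gene_counts if (c.Ps + c.Ds) > 0
    )
    den = sum(
        c.Ps * c.Dn / (c.Ps + c.Ds) for c in gene_counts if (c.Ps + c.Ds) > 0
    )
    if den == 0:
        raise UndefinedStatisticError("weighted NI undefined (zero denominator)")
    return num / den


def expected_excess_nonsyn(counts: MKCounts) -> float:
    """Observed minus expected nonsynonymous SNPs: Pn - Ps*(Dn/Ds)."""
    if counts.Ds == 0:
        raise UndefinedStatisticError(
            f"{counts.gene_id}: excess undefined (Ds = 0)"
        )
    return counts.Pn - counts.Ps * (counts.Dn / counts.Ds)
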
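"""Expected elevation of linked neutral diversity near a balanced polymorphism.

At recombination distance r from a site under long-term balancing selection,
neutral diversity is elevated by the factor

    f(d) = 1 + 1 / (4 N r_bp d (1 - F)),

where N is the effective population size, r_bp the per-base-pair per-
generation recombination rate, d the distance in base pairs, and F the
inbreeding coefficient, which discounts the effective recombination rate
under selfing.  When F is not given it is derived from the outcrossing rate
o at the partial-selfing equilibrium F = (1 - o)/(1 + o), i.e.
1 - F = 2o/(1 + o).  The inverse gives the distance at which a target
elevation factor is reached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional


@dataclass
class TheoryParams:
    N: float  # effective population size
    r_bp: float  # recombination rate per bp per generation
    o: float = 0.0  # outcrossing rate per generation
    F: Optional[float] = None  # inbreeding coefficient; derived from o if None

    def __post_init__(self):
        if self.N <= 0:
            raise ValueError("N must be positive")
        if self.r_bp < 0:
            raise ValueError("r_bp must be nonnegative")
        if not (0 <= self.o <= 1):
            raise ValueError("o must be in [0, 1]")
        if self.F is not None and not (0 <= self.F <= 1):
            raise ValueError("F must be in [0, 1]")

    @property
    def one_minus_F(self) -> float:
        if self.F is not None:
            return 1.0 - self.F
        return 2.0 * self.o / (1.0 + self.o)


def relative_diversity_factor(d: float, params: TheoryParams) -> float:
    """Diversity at distance ``d`` bp relative to an unlinked neutral locus."""
    if d < 0:
        raise ValueError("distance must be nonnegative")
    denom = 4.0 * params.N * params.r_bp * d * params.one_minus_F
    if denom == 0.0:
        return math.inf
    return 1.0 + 1.0 / denom


def distance_for_factor(factor: float, params: TheoryParams) -> float:
    """Distance (bp) at which diversity is elevated by ``factor``."""
    if factor <= 1.0:
        raise ValueError("factor must exceed 1")
    denom = 4.0 * params.N * params.r_bp * params.one_minus_F * (factor - 1.0)
    if denom == 0.0:
        return math.inf
    return 1.0 / denom
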
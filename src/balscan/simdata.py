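"""Synthetic codon alignments with the structure the analyses assume.

The generator builds a random in-frame ancestral coding sequence and places
segregating variants and outgroup substitutions on it, infinite-sites style
(at most one mutation per codon, no back-mutation), so that every generated
event is recoverable exactly by the codon classifier and the expected counts
are analytically checkable:

* segregating synonymous / nonsynonymous variants arrive as
  Poisson(k θ a(n)) with a(n) = Σ_{j<n} 1/j, each carried by i strains with
  the neutral site-frequency law P(i) ∝ 1/i;
* ``deleterious_excess`` mode reweights nonsynonymous variants toward
  singletons: with probability ``rare_bias`` a nonsynonymous variant is
  forced to i = 1 (mimicking weak purifying selection);
* ``balanced`` mode splits the sample into 2–3 haplotype groups and places
  Poisson(τ) extra variants per group per class on the group stems
  (carrier set = the whole group), producing the deep structure and
  intermediate-frequency excess a balanced polymorphism maintains; the
  selection scalar ``k`` multiplies the polymorphism rate, matching the
  ML-HKA parameterisation;
* the outgroup lineage receives Poisson(θ (T_div + (1+k)/2)) substitutions
  per class, so fixed differences and polymorphism are disjoint by
  construction and the divergence model matches the HKA likelihood.

Synonymous/nonsynonymous placement respects the genetic code (rejection
sampling on the mutation type; changes to stop codons are never produced),
so generated alignments pass curation unchanged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .codon_counts import GENETIC_CODE, NUCS, SENSE_CODONS
from .curation import GeneAlignment
from .diversity import harmonic
from .exceptions import BalscanError, ConfigurationError


@dataclass
class SimConfig:
    n: int = 24  # ingroup sample size
    L: int = 371  # codons
    theta_syn: float = 8.0  # per-locus population mutation rate, syn class
    theta_nonsyn: float = 8.0
    T_div: float = 5.0  # divergence depth, coalescent units
    mode: str = "neutral"  # neutral | deleterious_excess | balanced
    groups: Optional[tuple] = None  # (sizes, tau): stem-variant rate per group;
    # tau may be a scalar (both classes) or a (tau_syn, tau_nonsyn) pair
    rare_bias: float = 0.6  # deleterious mode: P(force nonsyn variant to singleton)
    k: float = 1.0  # selection scalar on polymorphism (1 = neutral)
    nonsyn_fixation: float = 1.0  # fraction of nonsyn mutations free to fix:
    # scales nonsynonymous divergence only (purifying constraint on fixation,
    # while deleterious/balanced variants still contribute to polymorphism)
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("neutral", "deleterious_excess", "balanced"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.theta_syn < 0 or self.theta_nonsyn < 0 or self.T_div < 0:
            raise ConfigurationError("rates must be nonnegative")
        if not (0 <= self.rare_bias <= 1):
            raise ConfigurationError("rare_bias must be in [0, 1]")
        if self.k <= 0:
            raise ConfigurationError("k must be positive")
        if not (0 <= self.nonsyn_fixation):
            raise ConfigurationError("nonsyn_fixation must be nonnegative")
        if self.mode == "balanced" and self.groups is None:
            # three roughly equal groups by default, mirroring a deep
            # 3-haplotype balanced polymorphism
            base = self.n // 3
            sizes = [base, base, self.n - 2 * base]
            self.groups = (sizes, 4.0)
        if self.groups is not None:
            sizes, tau = self.groups
            if sum(sizes) != self.n:
                raise ConfigurationError("group sizes must sum to n")
            tau_pair = tau if isinstance(tau, (tuple, list)) else (tau, tau)
            if min(tau_pair) < 0:
                raise ConfigurationError("tau must be nonnegative")


_SYN_CHANGES: dict = {}
_NONSYN_CHANGES: dict = {}
for _c in SENSE_CODONS:
    syn, non = [], []
    for _p in range(3):
        for _alt in NUCS:
            if _alt == _c[_p]:
                continue
            _m = _c[:_p] + _alt + _c[_p + 1 :]
            if GENETIC_CODE[_m] == "*":
                continue
            (syn if GENETIC_CODE[_m] == GENETIC_CODE[_c] else non).append((_p, _alt))
    _SYN_CHANGES[_c] = syn
    _NONSYN_CHANGES[_c] = non


def _neutral_count(rng, n: int) -> int:
    """Derived-allele count i in 1..n-1 with P(i) proportional to 1/i."""
    w = 1.0 / np.arange(1, n)
    return int(rng.choice(np.arange(1, n), p=w / w.sum()))


def simulate_locus(cfg: SimConfig, gene_id: str = "sim") -> GeneAlignment:
    """Generate one curated-grade codon alignment (+outgroup) from ``cfg``."""
    rng = np.random.default_rng(cfg.seed)
    n, L = cfg.n, cfg.L
    ancestral = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), L)]

    a_n = harmonic(n - 1)
    anc_term = (1.0 + cfg.k) / 2.0
    n_syn = rng.poisson(cfg.k * cfg.theta_syn * a_n)
    n_nonsyn = rng.poisson(cfg.k * cfg.theta_nonsyn * a_n)
    d_syn = rng.poisson(cfg.theta_syn * (cfg.T_div + anc_term))
    d_nonsyn = rng.poisson(
        cfg.nonsyn_fixation * cfg.theta_nonsyn * (cfg.T_div + anc_term)
    )

    group_of = None
    stem_events: list[tuple[str, int]] = []  # (class, group index)
    if cfg.mode == "balanced":
        sizes, tau = cfg.groups
        tau_syn, tau_nonsyn = tau if isinstance(tau, (tuple, list)) else (tau, tau)
        group_of = np.repeat(np.arange(len(sizes)), sizes)
        for g in range(len(sizes)):
            for _ in range(rng.poisson(tau_syn)):
                stem_events.append(("syn", g))
            for _ in range(rng.poisson(tau_nonsyn)):
                stem_events.append(("nonsyn", g))

    # event list: (class, kind, payload); kind in {poly, stem, fixed}
    events: list[tuple[str, str, int]] = []
    events += [("syn", "poly", -1)] * n_syn
    events += [("nonsyn", "poly", -1)] * n_nonsyn
    events += [(cls, "stem", g) for cls, g in stem_events]
    events += [("syn", "fixed", -1)] * d_syn
    events += [("nonsyn", "fixed", -1)] * d_nonsyn

    free = list(rng.permutation(L))
    ingroup = np.tile(np.array(ancestral, dtype="U3"), (n, 1))
    outgroup = np.array(ancestral, dtype="U3")

    for cls, kind, g in events:
        table = _SYN_CHANGES if cls == "syn" else _NONSYN_CHANGES
        placed = False
        unsuitable = []  # codons lacking a neighbor of this class; returned
        while free:
            j = free.pop()
            options = table[ancestral[j]]
            if not options:
                unsuitable.append(j)
                continue
            pos, alt = options[int(rng.integers(len(options)))]
            derived = ancestral[j][:pos] + alt + ancestral[j][pos + 1 :]
            if kind == "fixed":
                outgroup[j] = derived
            else:
                if kind == "stem":
                    carriers = np.flatnonzero(group_of == g)
                else:
                    i = _neutral_count(rng, n)
                    if (
                        cfg.mode == "deleterious_excess"
                        and cls == "nonsyn"
                        and rng.random() < cfg.rare_bias
                    ):
                        i = 1
                    carriers = rng.choice(n, size=i, replace=False)
                ingroup[carriers, j] = derived
            placed = True
            break
        free = unsuitable[::-1] + free
        if not placed:
            raise BalscanError(
                f"{gene_id}: could not place all {len(events)} mutations on "
                f"{L} codons (locus saturated)"
            )

    records = [
        (f"s{i:02d}", "".join(ingroup[i])) for i in range(n)
    ]
    return GeneAlignment(
        gene_id=gene_id,
        records=records,
        reference_id="s00",
        outgroup=("outgroup", "".join(outgroup)),
        frame_offset=0,
        curation_log=[],
    )


def _child_seeds(seed: int, count: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(count)]


def simulate_dataset(
    control_cfgs: Sequence[SimConfig],
    test_cfgs: Sequence[SimConfig],
    seed: int = 0,
) -> tuple[dict, list]:
    """Simulate an independent multi-locus dataset with derived seeds.

    Returns ``(alignments, manifest)``: a gene_id -> GeneAlignment mapping
    (controls named c00, c01, ... and test loci t00, t01, ...) and a truth
    manifest recording each locus's mode and parameters for recovery scoring.
    """
    if not control_cfgs:
        raise ConfigurationError("need at least one control locus")
    cfgs = [("c%02d" % i, c) for i, c in enumerate(control_cfgs)]
    cfgs += [("t%02d" % i, c) for i, c in enumerate(test_cfgs)]
    seeds = _child_seeds(seed, len(cfgs))
    alignments = {}
    manifest = []
    for (gid, cfg), s in zip(cfgs, seeds):
        cfg = dataclasses.replace(cfg, seed=s)
        alignments[gid] = simulate_locus(cfg, gene_id=gid)
        manifest.append(
            {
                "gene_id": gid,
                "role": "control" if gid.startswith("c") else "test",
                "mode": cfg.mode,
                "n": cfg.n,
                "L": cfg.L,
                "theta_syn": cfg.theta_syn,
                "theta_nonsyn": cfg.theta_nonsyn,
                "T_div": cfg.T_div,
                "k": cfg.k,
                "nonsyn_fixation": cfg.nonsyn_fixation,
                "rare_bias": cfg.rare_bias,
                "groups": None if cfg.groups is None else
                    {"sizes": list(cfg.groups[0]), "tau": cfg.groups[1]},
                "seed": s,
            }
        )
    return alignments, manifest
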
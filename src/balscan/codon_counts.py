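"""Codon-level classification of polymorphism and divergence.

Given a curated in-frame alignment with one outgroup sequence, every variable
codon is decomposed into single-nucleotide changes and each change is labelled

* polymorphic (variable within the ingroup) vs fixed (ingroup monomorphic but
  different from the outgroup), and
* synonymous vs nonsynonymous, by translating the change in its codon context.

Codons hit by more than one change are handled with the Nei–Gojobori pathway
convention: all orderings of the single-base steps between the two codons are
enumerated, orderings passing through a stop codon are discarded, and the
synonymous/nonsynonymous fractions are averaged over the remainder.  A codon
whose ingroup haplotypes differ at two or more positions that do not vary
independently (the observed codons are not the Cartesian product of the
per-position alleles) cannot be decomposed and is labelled ``complex``;
complex codons are reported but excluded from the MK tallies.

Site totals follow the Nei–Gojobori convention: each codon position
contributes the fraction of its nine possible single-nucleotide changes that
are synonymous, averaged over the ingroup strains.

Gap handling is complete deletion at codon granularity: a codon containing a
gap or ``N`` in any retained strain (outgroup included) is excluded from all
tallies, which makes the counts reproducible and order-independent.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .curation import GeneAlignment, STOP_CODONS
from .exceptions import BalscanError, ConfigurationError, UndefinedStatisticError

NUCS = "ACGT"

GENETIC_CODE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    GENETIC_CODE[_stop] = "*"

SENSE_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")

#: Standard S. cerevisiae optimal ("preferred") codons — the major codon of
#: each amino-acid family under translational selection; single-codon families
#: (Met, Trp) are trivially preferred.  Overridable in every consumer.
DEFAULT_PREFERRED_CODONS = frozenset(
    {
        "TTC", "TTG", "ATT", "ATC", "GTT", "GTC", "TCT", "TCC", "CCA",
        "ACT", "ACC", "GCT", "GCC", "TAC", "CAC", "CAA", "AAC", "AAG",
        "GAC", "GAA", "TGT", "CGT", "AGA", "GGT", "ATG", "TGG",
    }
)


def default_preference_table() -> dict[str, str]:
    """Codon -> 'preferred' | 'unpreferred' over all 61 sense codons."""
    return {
        c: ("preferred" if c in DEFAULT_PREFERRED_CODONS else "unpreferred")
        for c in SENSE_CODONS
    }


def translate(codon: str) -> str:
    return GENETIC_CODE[codon]


@lru_cache(maxsize=None)
def codon_syn_fraction(codon: str) -> float:
    """Number of synonymous sites in a codon (0..3, Nei–Gojobori).

    Each position contributes the fraction of its three single-nucleotide
    changes that preserve the amino acid; changes to stop codons count as
    nonsynonymous.
    """
    if GENETIC_CODE[codon] == "*":
        raise BalscanError(f"stop codon {codon} has no site counts")
    total = 0.0
    for pos in range(3):
        syn = 0
        for alt in NUCS:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if GENETIC_CODE[mutant] == GENETIC_CODE[codon]:
                syn += 1
        total += syn / 3.0
    return total


@lru_cache(maxsize=None)
def pathway_fractions(c1: str, c2: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) change counts between two codons.

    Enumerates every ordering of the single-base steps turning ``c1`` into
    ``c2``, drops orderings whose intermediate codons are stops, and averages
    the per-step classifications over the remaining orderings.  If every
    ordering is blocked by a stop, all orderings are used (the standard
    fallback — the data then contain an unavoidable stop-passing path).
    """
    diff = [p for p in range(3) if c1[p] != c2[p]]
    if not diff:
        return (0.0, 0.0)
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in itertools.permutations(diff):
        cur = c1
        syn = non = 0
        hit_stop = False
        for step, p in enumerate(order):
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            # only intermediate codons can block; the endpoint is the datum
            if GENETIC_CODE[nxt] == "*" and step < len(order) - 1:
                hit_stop = True
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                syn += 1
            else:
                non += 1
            cur = nxt
        (blocked if hit_stop else valid).append((syn, non))
    pool = valid if valid else blocked
    s = sum(x for x, _ in pool) / len(pool)
    n = sum(y for _, y in pool) / len(pool)
    return (s, n)


@dataclass(frozen=True)
class SiteCall:
    """One classified change (or one undecomposable codon)."""

    codon_index: int  # 0-based
    category: str  # syn_poly | nonsyn_poly | syn_fixed | nonsyn_fixed | complex
    minor_count: int
    carrier_set: frozenset
    polarized: bool
    position_in_codon: Optional[int] = None  # 0..2, None for complex
    derived_count: Optional[int] = None
    ancestral_codon: Optional[str] = None
    derived_codon: Optional[str] = None
    note: str = ""

    @property
    def is_polymorphic(self) -> bool:
        return self.category in ("syn_poly", "nonsyn_poly", "complex")


@dataclass
class MKCounts:
    """The 2x2 MK table plus site totals for one gene.

    ``Dn``/``Ds`` are integer tallies (pathway-averaged fractions rounded at
    reporting time); the unrounded accumulators are kept in ``dn_exact`` and
    ``ds_exact``.
    """

    gene_id: str
    Pn: int
    Ps: int
    Dn: int
    Ds: int
    n_sites: int
    syn_sites: float
    nonsyn_sites: float
    n_strains: int
    dn_exact: float = 0.0
    ds_exact: float = 0.0
    n_complex: int = 0


@dataclass
class Sfs:
    """Folded (or, when polarized, derived) site-frequency spectrum."""

    n: int
    counts: dict  # allele count -> number of variants

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _analyzed_codons(aln: GeneAlignment, require_outgroup: bool):
    """Codon indices passing complete deletion, with the codon matrix."""
    ids, M = aln.codon_matrix(include_outgroup=require_outgroup)
    n = aln.n_strains
    if require_outgroup:
        if aln.outgroup is None:
            raise BalscanError(
                f"{aln.gene_id}: outgroup required for divergence counts"
            )
        ing, outg = M[:n], M[n]
    else:
        M = M[:n]
        ing, outg = M, None
    ncod = M.shape[1] // 3
    valid = np.isin(M, list(NUCS)).all(axis=0).reshape(ncod, 3).all(axis=1)
    # exclude a terminal reference stop codon from all analyses
    ref_row = aln.strain_ids.index(aln.reference_id)
    if ncod > 0:
        last = "".join(ing[ref_row, 3 * (ncod - 1) : 3 * ncod])
        if last in STOP_CODONS:
            valid[ncod - 1] = False
    return ids, ing, outg, valid


def count_syn_nonsyn_sites(
    aln: GeneAlignment, codon_indices: Optional[Iterable[int]] = None
) -> tuple[float, float]:
    """Nei–Gojobori synonymous/nonsynonymous site totals (ingroup average)."""
    _, ing, _, valid = _analyzed_codons(aln, require_outgroup=False)
    ncod = ing.shape[1] // 3
    indices = range(ncod) if codon_indices is None else codon_indices
    syn = nonsyn = 0.0
    for j in indices:
        fracs = []
        for row in ing:
            codon = "".join(row[3 * j : 3 * j + 3])
            if any(c not in NUCS for c in codon):
                continue
            if GENETIC_CODE[codon] == "*":
                raise BalscanError(
                    f"{aln.gene_id}: stop codon {codon} at codon {j + 1} "
                    "(should have been curated away)"
                )
            fracs.append(codon_syn_fraction(codon))
        if not fracs:
            continue
        s = float(np.mean(fracs))
        syn += s
        nonsyn += 3.0 - s
    return syn, nonsyn


def _majority(chars: Sequence[str]) -> str:
    counts = Counter(chars)
    return min(counts, key=lambda c: (-counts[c], c))


def _poly_call(
    j: int,
    pos: int,
    context: str,
    col: Sequence[str],
    out_allele: Optional[str],
    strain_ids: Sequence[str],
) -> SiteCall:
    """Classify one polymorphic position within a codon context."""
    counts = Counter(col)
    n = len(col)
    major = min(counts, key=lambda c: (-counts[c], c))
    if len(counts) == 2:
        minor = next(c for c in counts if c != major)
        c_major = context[:pos] + major + context[pos + 1 :]
        c_minor = context[:pos] + minor + context[pos + 1 :]
        syn = GENETIC_CODE[c_major] == GENETIC_CODE[c_minor]
        category = "syn_poly" if syn else "nonsyn_poly"
        polarized = out_allele in counts if out_allele is not None else False
        note = ""
        if polarized:
            derived = minor if out_allele == major else major
            derived_count = counts[derived]
            carriers = frozenset(
                sid for sid, c in zip(strain_ids, col) if c == derived
            )
            anc = context[:pos] + (major if derived == minor else minor) + context[pos + 1 :]
            der = context[:pos] + derived + context[pos + 1 :]
        else:
            derived_count = None
            carriers = frozenset(
                sid for sid, c in zip(strain_ids, col) if c == minor
            )
            anc = der = None
        return SiteCall(
            codon_index=j,
            category=category,
            minor_count=min(counts.values()),
            carrier_set=carriers,
            polarized=polarized,
            position_in_codon=pos,
            derived_count=derived_count,
            ancestral_codon=anc,
            derived_codon=der,
            note=note,
        )
    # tri-allelic (or more): one polymorphic site; class from the most
    # parsimonious pathway set (each non-major allele as a change from the
    # major allele), ties broken toward synonymous.
    c_major = context[:pos] + major + context[pos + 1 :]
    syn_ct = non_ct = 0
    for allele in counts:
        if allele == major:
            continue
        c_alt = context[:pos] + allele + context[pos + 1 :]
        if GENETIC_CODE[c_alt] == GENETIC_CODE[c_major]:
            syn_ct += 1
        else:
            non_ct += 1
    category = "syn_poly" if syn_ct >= non_ct else "nonsyn_poly"
    note = "triallelic" + (";tie->syn" if syn_ct == non_ct and non_ct > 0 else "")
    carriers = frozenset(sid for sid, c in zip(strain_ids, col) if c != major)
    return SiteCall(
        codon_index=j,
        category=category,
        minor_count=len(carriers),
        carrier_set=carriers,
        polarized=False,
        position_in_codon=pos,
        note=note,
    )


def classify_variants(
    aln: GeneAlignment, require_outgroup: bool = True
) -> tuple[list[SiteCall], MKCounts]:
    """Classify every variable codon and tally the MK table.

    Requires an outgroup by default (fixed differences are defined against
    it); with ``require_outgroup=False`` and no outgroup present, only the
    polymorphism classes are produced (Dn = Ds = 0, nothing polarized).  A
    position polymorphic in the ingroup counts as polymorphic only, even if
    every ingroup allele differs from the outgroup; a fixed difference
    requires ingroup monomorphism at that position.
    """
    has_outgroup = aln.outgroup is not None
    if require_outgroup and not has_outgroup:
        raise BalscanError(
            f"{aln.gene_id}: outgroup required for divergence counts"
        )
    ids, ing, outg, valid = _analyzed_codons(aln, require_outgroup=has_outgroup)
    strain_ids = ids[: aln.n_strains]
    n = aln.n_strains
    ncod = ing.shape[1] // 3

    analyzed = np.flatnonzero(valid)
    # quick vectorized scan for codons with any variation (ingroup or outgroup)
    allrows = np.vstack([ing, outg[None, :]]) if outg is not None else ing
    var_col = (allrows != allrows[0]).any(axis=0)
    var_codon = var_col.reshape(ncod, 3).any(axis=1)

    calls: list[SiteCall] = []
    pn = ps = 0
    dn_exact = ds_exact = 0.0
    n_complex = 0

    for j in analyzed:
        if not var_codon[j]:
            continue
        cod_cols = [ing[:, 3 * j + p] for p in range(3)]
        out_codon = None if outg is None else "".join(outg[3 * j : 3 * j + 3])
        allele_sets = [set(c.tolist()) for c in cod_cols]
        P = [p for p in range(3) if len(allele_sets[p]) > 1]
        if out_codon is None:
            F = []
        else:
            F = [
                p
                for p in range(3)
                if len(allele_sets[p]) == 1
                and next(iter(allele_sets[p])) != out_codon[p]
            ]
        if not P and not F:
            continue
        consensus = "".join(_majority(cod_cols[p].tolist()) for p in range(3))

        if len(P) >= 2:
            observed = {
                tuple(ing[i, 3 * j + p] for p in P) for i in range(n)
            }
            product_size = 1
            for p in P:
                product_size *= len(allele_sets[p])
            if len(observed) != product_size:
                # linked multi-position polymorphism: undecomposable;
                # carriers are the strains off the majority haplotype
                full_codons = ["".join(ing[i, 3 * j : 3 * j + 3]) for i in range(n)]
                major_codon = _majority(full_codons)
                carriers = frozenset(
                    strain_ids[i] for i in range(n)
                    if full_codons[i] != major_codon
                )
                calls.append(
                    SiteCall(
                        codon_index=int(j),
                        category="complex",
                        minor_count=len(carriers),
                        carrier_set=carriers,
                        polarized=False,
                        note=f"{len(P)} linked polymorphic positions",
                    )
                )
                n_complex += 1
                continue

        # independent polymorphic positions, evaluated in consensus context
        for p in P:
            call = _poly_call(
                int(j), p, consensus, cod_cols[p].tolist(),
                None if out_codon is None else out_codon[p], strain_ids,
            )
            calls.append(call)
            if call.category == "syn_poly":
                ps += 1
            else:
                pn += 1

        # fixed differences, pathway-averaged between the ingroup consensus
        # and the codon with outgroup alleles substituted at F positions
        if F:
            start = consensus
            end = "".join(
                out_codon[p] if p in F else consensus[p] for p in range(3)
            )
            syn_f, non_f = pathway_fractions(start, end)
            ds_exact += syn_f
            dn_exact += non_f
            for p in F:
                single = start[:p] + out_codon[p] + start[p + 1 :]
                syn1 = GENETIC_CODE[single] == GENETIC_CODE[start]
                calls.append(
                    SiteCall(
                        codon_index=int(j),
                        category="syn_fixed" if syn1 else "nonsyn_fixed",
                        minor_count=0,
                        carrier_set=frozenset(),
                        polarized=True,
                        position_in_codon=p,
                        ancestral_codon=end,
                        derived_codon=start,
                        note="multihit" if len(F) > 1 else "",
                    )
                )

    syn_sites, nonsyn_sites = count_syn_nonsyn_sites(aln, analyzed.tolist())
    counts = MKCounts(
        gene_id=aln.gene_id,
        Pn=pn,
        Ps=ps,
        Dn=int(round(dn_exact)),
        Ds=int(round(ds_exact)),
        n_sites=3 * len(analyzed),
        syn_sites=syn_sites,
        nonsyn_sites=nonsyn_sites,
        n_strains=n,
        dn_exact=dn_exact,
        ds_exact=ds_exact,
        n_complex=n_complex,
    )
    return calls, counts


_CATEGORY_SELECTORS = {
    "synonymous": ("syn_poly",),
    "nonsynonymous": ("nonsyn_poly",),
    "syn_poly": ("syn_poly",),
    "nonsyn_poly": ("nonsyn_poly",),
}


def sfs_fraction_below(
    calls: Sequence[SiteCall], category: str, threshold: float, n: int
) -> tuple[Sfs, float]:
    """Site-frequency spectrum of one class and the share of rare variants.

    A variant counts as rare when its allele frequency (derived count over
    ``n`` when polarized, else minor count over ``n``) is strictly below
    ``threshold``.
    """
    try:
        wanted = _CATEGORY_SELECTORS[category]
    except KeyError:
        raise ConfigurationError(f"unknown category selector {category!r}")
    counts: Counter = Counter()
    for call in calls:
        if call.category not in wanted or not call.is_polymorphic:
            continue
        c = call.derived_count if (call.polarized and call.derived_count) else call.minor_count
        counts[c] += 1
    if not counts:
        raise UndefinedStatisticError(
            f"no polymorphic calls of class {category!r}"
        )
    sfs = Sfs(n=n, counts=dict(sorted(counts.items())))
    below = sum(v for c, v in counts.items() if c / n < threshold)
    return sfs, below / sfs.total


@dataclass
class PreferenceChanges:
    poly_to_pref: int = 0
    poly_to_unpref: int = 0
    div_to_pref: int = 0
    div_to_unpref: int = 0
    skipped: int = 0


def codon_preference_changes(
    calls: Sequence[SiteCall],
    aln: GeneAlignment,
    preference: Optional[dict] = None,
) -> PreferenceChanges:
    """Tally synonymous changes by the preference class of the derived codon.

    Polymorphisms are polarized by the outgroup; fixed differences are
    attributed to the ingroup lineage (ingroup codon = derived), the standard
    single-outgroup convention.  Unpolarizable synonymous changes are skipped
    and counted in ``skipped``.
    """
    if preference is None:
        preference = default_preference_table()
    out = PreferenceChanges()
    for call in calls:
        if call.category not in ("syn_poly", "syn_fixed"):
            continue
        if not call.polarized or call.derived_codon is None:
            out.skipped += 1
            continue
        try:
            cls = preference[call.derived_codon]
        except KeyError:
            raise ConfigurationError(
                f"preference table missing codon {call.derived_codon!r}"
            )
        if call.category == "syn_poly":
            if cls == "preferred":
                out.poly_to_pref += 1
            else:
                out.poly_to_unpref += 1
        else:
            if cls == "preferred":
                out.div_to_pref += 1
            else:
                out.div_to_unpref += 1
    return out
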
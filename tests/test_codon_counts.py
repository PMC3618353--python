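"""Codon classification, site counting, spectra and preference tallies."""

import itertools

import numpy as np
import pytest

from balscan.codon_counts import (
    GENETIC_CODE,
    classify_variants,
    codon_preference_changes,
    count_syn_nonsyn_sites,
    default_preference_table,
    sfs_fraction_below,
)
from balscan.exceptions import UndefinedStatisticError

from conftest import make_aln

NUCS = "ACGT"


def codons(*cods):
    return "".join(cods)


# ---------------------------------------------------------------------------
# hand-translated examples
# ---------------------------------------------------------------------------

def test_synonymous_fixed_difference():
    # CTT and CTG are both Leu
    aln = make_aln([codons("CTT")] * 4, outgroup=codons("CTG"))
    calls, c = classify_variants(aln)
    assert (c.Pn, c.Ps, c.Dn, c.Ds) == (0, 0, 0, 1)
    assert len(calls) == 1 and calls[0].category == "syn_fixed"


def test_nonsynonymous_polymorphism_polarized():
    # GAT = Asp, GAA = Glu; outgroup matches the major allele
    aln = make_aln(["GAT", "GAT", "GAA", "GAT"], outgroup="GAT")
    calls, c = classify_variants(aln)
    assert (c.Pn, c.Ps, c.Dn, c.Ds) == (1, 0, 0, 0)
    call = calls[0]
    assert call.category == "nonsyn_poly"
    assert call.minor_count == 1
    assert call.polarized and call.derived_count == 1
    assert call.derived_codon == "GAA"


def test_invariant_alignment_yields_nothing():
    aln = make_aln(["ATGGCT"] * 5, outgroup="ATGGCT")
    calls, c = classify_variants(aln)
    assert calls == [] and (c.Pn, c.Ps, c.Dn, c.Ds) == (0, 0, 0, 0)


def test_polymorphic_site_not_double_counted_as_divergence():
    # ingroup segregates A/G; outgroup carries a third state: polymorphism only
    aln = make_aln(["GGT", "GGT", "AGT", "AGT"], outgroup="CGT")
    calls, c = classify_variants(aln)
    assert c.Dn + c.Ds == 0
    assert c.Pn + c.Ps == 1


def test_gapped_codon_excluded_completely():
    aln = make_aln(["CTTGAT", "CT-GAT", "CTTGAT"], outgroup="CTGGAT")
    _, c = classify_variants(aln)
    # first codon has a gap in one strain: its fixed difference is not counted
    assert (c.Pn, c.Ps, c.Dn, c.Ds) == (0, 0, 0, 0)
    assert c.n_sites == 3


def test_site_counts_ttt():
    aln = make_aln(["TTT"] * 3, outgroup="TTT")
    syn, nonsyn = count_syn_nonsyn_sites(aln)
    assert syn == pytest.approx(1 / 3)
    assert nonsyn == pytest.approx(8 / 3)


def test_site_counts_atg_has_no_synonymous_sites():
    aln = make_aln(["ATGATG"] * 3, outgroup="ATGATG")
    syn, nonsyn = count_syn_nonsyn_sites(aln)
    assert syn == 0.0
    assert nonsyn == pytest.approx(6.0)


def test_site_counts_average_over_strains():
    # strains carry TTT and TTA at the same codon; counts are the brute-force
    # per-strain average
    def f(codon):
        syn = 0.0
        for p in range(3):
            s = sum(
                1
                for alt in NUCS
                if alt != codon[p]
                and GENETIC_CODE[codon[:p] + alt + codon[p + 1 :]]
                == GENETIC_CODE[codon]
            )
            syn += s / 3
        return syn

    aln = make_aln(["TTT", "TTA"], outgroup="TTT")
    syn, nonsyn = count_syn_nonsyn_sites(aln)
    expected = (f("TTT") + f("TTA")) / 2
    assert syn == pytest.approx(expected)
    assert syn + nonsyn == pytest.approx(3.0)


def test_terminal_stop_codon_excluded():
    aln = make_aln(["ATGTAA"] * 3, outgroup="ATGTAA")
    calls, c = classify_variants(aln)
    assert c.n_sites == 3  # only the ATG codon is analyzed


# ---------------------------------------------------------------------------
# invariances
# ---------------------------------------------------------------------------

def test_p_counts_do_not_depend_on_outgroup():
    seqs = ["GATCTT", "GAACTT", "GATCTT", "GATCTG"]
    a1 = make_aln(seqs, outgroup="GATCTT")
    a2 = make_aln(seqs, outgroup="CATAGG")
    _, c1 = classify_variants(a1)
    _, c2 = classify_variants(a2)
    assert (c1.Pn, c1.Ps) == (c2.Pn, c2.Ps)


def test_d_counts_do_not_depend_on_polymorphism_elsewhere():
    base = ["CTTGAT"] * 4
    poly = ["CTTGAT", "CTTGAA", "CTTGAT", "CTTGAT"]
    out = "CTGGAT"
    _, c1 = classify_variants(make_aln(base, outgroup=out))
    _, c2 = classify_variants(make_aln(poly, outgroup=out))
    assert (c1.Dn, c1.Ds) == (c2.Dn, c2.Ds)


def test_swapping_single_ingroup_and_outgroup_preserves_divergence():
    a = make_aln(["CTTGATAAA"], outgroup="CTGGAAAAA")
    b = make_aln(["CTGGAAAAA"], outgroup="CTTGATAAA")
    _, ca = classify_variants(a)
    _, cb = classify_variants(b)
    assert ca.Dn + ca.Ds == cb.Dn + cb.Ds


# ---------------------------------------------------------------------------
# multi-hit codons
# ---------------------------------------------------------------------------

def test_two_hit_fixed_difference_uses_pathway_average():
    # TTT (Phe) vs GTA (Val): positions 1 and 3 differ.
    # Pathways: TTT->GTT(non)->GTA(syn) and TTT->TTA(non)->GTA(non)
    # average: 0.5 syn, 1.5 nonsyn
    aln = make_aln(["TTT"] * 3, outgroup="GTA")
    calls, c = classify_variants(aln)
    assert c.ds_exact == pytest.approx(0.5)
    assert c.dn_exact == pytest.approx(1.5)
    assert c.Dn + c.Ds == 2  # rounded at reporting time


def test_linked_double_polymorphism_is_complex():
    # two haplotypes differing at two codon positions; combinations AT/GC only
    aln = make_aln(["ATT", "ATT", "GCT", "GCT"], outgroup="ATT")
    calls, c = classify_variants(aln)
    assert len(calls) == 1 and calls[0].category == "complex"
    assert c.Pn + c.Ps == 0 and c.n_complex == 1
    assert calls[0].carrier_set == frozenset({"s02", "s03"})


def test_independent_double_polymorphism_decomposed():
    # both positions vary independently (all four combinations observed)
    aln = make_aln(["ATT", "GTT", "ACT", "GCT"], outgroup="ATT")
    calls, c = classify_variants(aln)
    cats = sorted(call.category for call in calls)
    assert len(calls) == 2 and all("poly" in x for x in cats)
    assert c.Pn + c.Ps == 2


def test_polymorphism_and_fixed_difference_in_one_codon():
    # position 1 polymorphic in the ingroup, position 3 fixed vs outgroup
    aln = make_aln(["CTT", "ATT", "CTT", "CTT"], outgroup="CTG")
    calls, c = classify_variants(aln)
    assert c.Pn + c.Ps == 1
    assert c.Dn + c.Ds == 1


# ---------------------------------------------------------------------------
# brute-force oracle on random alignments
# ---------------------------------------------------------------------------

def _oracle_counts(aln):
    """Naive per-codon reclassification: translate everything, enumerate
    pathways explicitly, follow the same decomposition conventions."""
    ids, M = aln.codon_matrix(include_outgroup=True)
    n = aln.n_strains
    ncod = M.shape[1] // 3
    pn = ps = 0
    dn = ds = 0.0
    for j in range(ncod):
        cods = ["".join(M[i, 3 * j : 3 * j + 3]) for i in range(n)]
        out = "".join(M[n, 3 * j : 3 * j + 3])
        if any(ch not in NUCS for cod in cods + [out] for ch in cod):
            continue
        if GENETIC_CODE[cods[0]] == "*" and j == ncod - 1:
            continue
        P = [p for p in range(3) if len({c[p] for c in cods}) > 1]
        F = [p for p in range(3)
             if len({c[p] for c in cods}) == 1 and cods[0][p] != out[p]]
        if len(P) >= 2:
            observed = {tuple(c[p] for p in P) for c in cods}
            full = 1
            for p in P:
                full *= len({c[p] for c in cods})
            if len(observed) != full:
                continue  # complex: excluded
        cons = ""
        for p in range(3):
            col = [c[p] for c in cods]
            cons += min(set(col), key=lambda x: (-col.count(x), x))
        for p in P:
            col = [c[p] for c in cods]
            alleles = sorted(set(col))
            major = min(alleles, key=lambda x: (-col.count(x), x))
            syn_ct = non_ct = 0
            for alt in alleles:
                if alt == major:
                    continue
                c1 = cons[:p] + major + cons[p + 1 :]
                c2 = cons[:p] + alt + cons[p + 1 :]
                if GENETIC_CODE[c1] == GENETIC_CODE[c2]:
                    syn_ct += 1
                else:
                    non_ct += 1
            if len(alleles) == 2:
                ps += syn_ct
                pn += non_ct
            else:
                if syn_ct >= non_ct:
                    ps += 1
                else:
                    pn += 1
        if F:
            start = cons
            end = "".join(out[p] if p in F else cons[p] for p in range(3))
            paths = []
            blocked = []
            for order in itertools.permutations(F):
                cur, s, x, stop = start, 0, 0, False
                for step, p in enumerate(order):
                    nxt = cur[:p] + end[p] + cur[p + 1 :]
                    if GENETIC_CODE[nxt] == "*" and step < len(order) - 1:
                        stop = True
                    if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                        s += 1
                    else:
                        x += 1
                    cur = nxt
                (blocked if stop else paths).append((s, x))
            pool = paths or blocked
            ds += sum(a for a, _ in pool) / len(pool)
            dn += sum(b for _, b in pool) / len(pool)
    return pn, ps, dn, ds


def _random_alignment(rng, n=6, ncod=30):
    from balscan.codon_counts import SENSE_CODONS

    anc = [SENSE_CODONS[i] for i in rng.integers(0, 61, ncod)]
    mat = [list(anc) for _ in range(n)]
    out = list(anc)
    for _ in range(25):
        j = int(rng.integers(ncod))
        p = int(rng.integers(3))
        alt = "ACGT"[int(rng.integers(4))]
        if rng.random() < 0.4:
            new = out[j][:p] + alt + out[j][p + 1 :]
            out[j] = new
        else:
            i = int(rng.integers(n))
            new = mat[i][j][:p] + alt + mat[i][j][p + 1 :]
            mat[i][j] = new
    # no internal stops in any ingroup strain (curation contract)
    for i in range(n):
        for j in range(ncod - 1):
            if GENETIC_CODE[mat[i][j]] == "*":
                mat[i][j] = anc[j]
    seqs = ["".join(row) for row in mat]
    return make_aln(seqs, outgroup="".join(out))


@pytest.mark.parametrize("seed", range(12))
def test_classifier_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(1000 + seed)
    aln = _random_alignment(rng)
    _, c = classify_variants(aln)
    pn, ps, dn, ds = _oracle_counts(aln)
    assert (c.Pn, c.Ps) == (pn, ps)
    assert c.dn_exact == pytest.approx(dn)
    assert c.ds_exact == pytest.approx(ds)


# ---------------------------------------------------------------------------
# site-frequency spectrum
# ---------------------------------------------------------------------------

def _fake_calls(counts, n, category="nonsyn_poly"):
    from balscan.codon_counts import SiteCall

    return [
        SiteCall(
            codon_index=i,
            category=category,
            minor_count=c,
            carrier_set=frozenset([f"s{i}"]),
            polarized=False,
        )
        for i, c in enumerate(counts)
    ]


def test_sfs_fraction_counts_rare_variants():
    calls = _fake_calls([1, 1, 10], n=20)
    sfs, frac = sfs_fraction_below(calls, "nonsynonymous", 0.10, n=20)
    assert sfs.total == 3
    assert frac == pytest.approx(2 / 3)


def test_singleton_in_twenty_is_below_ten_percent():
    _, frac = sfs_fraction_below(_fake_calls([1], 20), "nonsynonymous", 0.10, n=20)
    assert frac == 1.0


def test_intermediate_variants_are_not_rare():
    _, frac = sfs_fraction_below(
        _fake_calls([10, 10], 20), "nonsynonymous", 0.10, n=20
    )
    assert frac == 0.0


def test_empty_class_is_undefined_not_zero():
    with pytest.raises(UndefinedStatisticError):
        sfs_fraction_below([], "synonymous", 0.1, n=20)


# ---------------------------------------------------------------------------
# codon preference changes
# ---------------------------------------------------------------------------

def test_preference_change_toward_preferred_codon():
    # TCT (preferred Ser) derived, TCA (unpreferred) ancestral = outgroup
    aln = make_aln(["TCT", "TCT", "TCA", "TCA"], outgroup="TCA")
    calls, _ = classify_variants(aln)
    res = codon_preference_changes(calls, aln)
    assert res.poly_to_pref == 1 and res.poly_to_unpref == 0


def test_fixed_difference_attributed_to_ingroup_lineage():
    aln = make_aln(["TCT"] * 4, outgroup="TCA")
    calls, _ = classify_variants(aln)
    res = codon_preference_changes(calls, aln)
    assert res.div_to_pref == 1 and res.div_to_unpref == 0


def test_unpolarized_synonymous_change_skipped():
    # outgroup carries a third allele: the polymorphism cannot be polarized
    aln = make_aln(["CGT", "CGT", "CGC", "CGC"], outgroup="CGG")
    calls, _ = classify_variants(aln)
    res = codon_preference_changes(calls, aln)
    assert res.skipped == 1
    assert res.poly_to_pref + res.poly_to_unpref == 0


def test_preference_table_covers_all_sense_codons():
    table = default_preference_table()
    assert len(table) == 61
    assert set(table.values()) == {"preferred", "unpreferred"}
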
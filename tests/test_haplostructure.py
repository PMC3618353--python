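"""Distances, NJ trees, bootstrap, branch mapping and Rm."""

import itertools

import numpy as np
import pytest

from balscan.codon_counts import SiteCall
from balscan.exceptions import BalscanError
from balscan.haplostructure import (
    bootstrap_support,
    map_variants_to_branches,
    nj_tree,
    pairwise_distances,
    rm_min_recomb,
)

from conftest import make_aln


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def test_identical_sequences_zero_distance():
    ids, d = pairwise_distances(make_aln(["ACGT"] * 3))
    assert np.allclose(d, 0)


def test_pairwise_gap_removal():
    ids, d = pairwise_distances(make_aln(["A-CG", "AACG", "AACG"]))
    assert d[0, 1] == 0.0  # compared over 3 columns only


def test_simple_proportion_distance():
    ids, d = pairwise_distances(make_aln(["AAAA", "AATT", "AAAA"]))
    assert d[0, 1] == pytest.approx(0.5)


def test_pair_without_comparable_columns_is_an_error():
    with pytest.raises(BalscanError):
        pairwise_distances(make_aln(["AA--", "--AA", "AAAA"]))


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def test_three_taxa_closed_form():
    labels = ["A", "B", "C"]
    d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
    tree = nj_tree(d, labels)
    # v_A = (dAB + dAC - dBC)/2 = 1, v_B = 2, v_C = 3
    bl = tree.branch_lengths
    assert bl[tree.canonical({"A"})] == pytest.approx(1)
    assert bl[tree.canonical({"B"})] == pytest.approx(2)
    assert bl[tree.canonical({"C"})] == pytest.approx(3)


def test_four_taxon_additive_matrix_recovered_exactly():
    labels = ["A", "B", "C", "D"]
    d = np.array(
        [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], float
    )
    tree = nj_tree(d, labels)
    split = tree.canonical({"A", "B"})
    assert split in tree.bipartitions
    assert tree.branch_lengths[split] == pytest.approx(2)  # internal branch
    assert tree.branch_lengths[tree.canonical({"A"})] == pytest.approx(1)


def test_asymmetric_matrix_rejected():
    d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
    with pytest.raises(ValueError):
        nj_tree(d, ["a", "b", "c"])


def _random_additive_tree(rng, ntaxa):
    """Random binary topology with positive branch lengths; returns
    (distance matrix, set of nontrivial bipartitions)."""
    nodes = [({i}, None) for i in range(ntaxa)]  # (leafset, None)
    dist = np.zeros((ntaxa, ntaxa))
    # start from a star and repeatedly join random pairs, accumulating path
    # lengths; track leaf-to-root path lengths explicitly
    depth = {i: 0.0 for i in range(ntaxa)}
    clusters = [[i] for i in range(ntaxa)]
    splits = []
    while len(clusters) > 2:
        i, j = sorted(rng.choice(len(clusters), 2, replace=False))
        bi, bj = float(rng.uniform(0.2, 2.0)), float(rng.uniform(0.2, 2.0))
        for x in clusters[i]:
            for y in clusters[j]:
                dist[x, y] = dist[y, x] = depth[x] + bi + depth[y] + bj
        merged = clusters[i] + clusters[j]
        for x in clusters[i]:
            depth[x] += bi
        for y in clusters[j]:
            depth[y] += bj
        splits.append(frozenset(merged))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    bi, bj = float(rng.uniform(0.2, 2.0)), float(rng.uniform(0.2, 2.0))
    for x in clusters[0]:
        for y in clusters[1]:
            dist[x, y] = dist[y, x] = depth[x] + bi + depth[y] + bj
    return dist, splits


@pytest.mark.parametrize("seed", range(10))
def test_nj_recovers_random_additive_trees(seed):
    rng = np.random.default_rng(seed)
    ntaxa = int(rng.integers(4, 13))
    dist, splits = _random_additive_tree(rng, ntaxa)
    labels = [f"t{i}" for i in range(ntaxa)]
    tree = nj_tree(dist, labels)
    for split in splits:
        if len(split) in (1, ntaxa - 1, ntaxa):
            continue
        side = {f"t{i}" for i in split}
        assert tree.canonical(side) in tree.bipartitions


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _two_clade_alignment():
    # two invariant blocks perfectly separating {s00,s01} from {s02,s03}
    a = "AAAAACCCCC"
    b = "TTTTTGGGGG"
    return make_aln([a, a, b, b, "AAAAAGGGGG"])


def test_perfect_split_gets_full_support():
    aln = _two_clade_alignment()
    tree = bootstrap_support(aln, replicates=50, seed=3)
    split = tree.canonical({"s00", "s01"})
    assert split in tree.support
    assert tree.support[split] == 100.0


def test_single_replicate_support_is_binary():
    aln = _two_clade_alignment()
    tree = bootstrap_support(aln, replicates=1, seed=3)
    assert set(tree.support.values()) <= {0.0, 100.0}


def test_bootstrap_deterministic_under_seed():
    aln = _two_clade_alignment()
    t1 = bootstrap_support(aln, replicates=25, seed=11)
    t2 = bootstrap_support(aln, replicates=25, seed=11)
    assert t1.support == t2.support


def test_newick_output_parses():
    import io

    from Bio import Phylo

    aln = _two_clade_alignment()
    tree = bootstrap_support(aln, replicates=10, seed=1)
    parsed = Phylo.read(io.StringIO(tree.newick()), "newick")
    assert {t.name for t in parsed.get_terminals()} == set(aln.strain_ids)


# ---------------------------------------------------------------------------
# branch mapping
# ---------------------------------------------------------------------------

def _call(carriers, category="syn_poly", idx=0):
    return SiteCall(
        codon_index=idx,
        category=category,
        minor_count=len(carriers),
        carrier_set=frozenset(carriers),
        polarized=False,
    )


def _quartet_tree():
    d = np.array(
        [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], float
    )
    return nj_tree(d, ["a", "b", "c", "d"])


def test_clade_variant_maps_to_internal_branch():
    tree = _quartet_tree()
    mapping = map_variants_to_branches(tree, [_call({"a", "b"})])
    assert mapping.n_mapped == 1
    branch = list(mapping.assignments.values())[0]
    assert branch == tree.canonical({"a", "b"})


def test_conflicting_variant_is_homoplasious():
    tree = _quartet_tree()
    mapping = map_variants_to_branches(tree, [_call({"a", "c"})])
    assert mapping.n_homoplasious == 1


def test_mapped_plus_homoplasious_equals_total():
    tree = _quartet_tree()
    calls = [
        _call({"a"}, idx=0),
        _call({"a", "b"}, "nonsyn_poly", idx=1),
        _call({"a", "c"}, idx=2),
        _call({"b", "c", "d"}, idx=3),  # complement of {a}: maps
    ]
    mapping = map_variants_to_branches(tree, calls)
    assert mapping.n_mapped + mapping.n_homoplasious == len(calls)
    assert mapping.n_mapped == 3


def test_unknown_carrier_is_an_error():
    tree = _quartet_tree()
    with pytest.raises(BalscanError):
        map_variants_to_branches(tree, [_call({"zzz"})])


# ---------------------------------------------------------------------------
# four-gamete test / Rm
# ---------------------------------------------------------------------------

def test_two_gamete_pair_is_compatible():
    aln = make_aln(["AA", "AA", "TT", "TT"])
    pairs, rm = rm_min_recomb(aln)
    assert pairs == [] and rm == 0


def test_three_site_all_incompatible_gives_rm_two():
    # haplotypes 000, 011, 101, 110 over sites {0,1,2}
    aln = make_aln(["AAA", "ATT", "TAT", "TTA"])
    pairs, rm = rm_min_recomb(aln)
    assert len(pairs) == 3
    assert rm == 2


def test_triallelic_sites_skipped():
    aln = make_aln(["AAA", "ACA", "AGA", "AAA"])
    pairs, rm = rm_min_recomb(aln)
    assert pairs == [] and rm == 0


def _brute_force_rm(pairs):
    """Maximum number of pairwise-disjoint open intervals, by exhaustion."""
    best = 0
    for r in range(1, len(pairs) + 1):
        for subset in itertools.combinations(pairs, r):
            ok = True
            for (a1, b1), (a2, b2) in itertools.combinations(subset, 2):
                if max(a1, a2) < min(b1, b2):  # open intervals overlap
                    ok = False
                    break
            if ok:
                best = max(best, r)
    return best


@pytest.mark.parametrize("seed", range(8))
def test_rm_matches_bruteforce_interval_cover(seed):
    # draw until the instance is small enough for the exhaustive oracle
    rng = np.random.default_rng(200 + seed)
    while True:
        mat = rng.choice(["A", "T"], size=(6, 8), p=[0.8, 0.2])
        aln = make_aln(["".join(row) for row in mat])
        pairs, rm = rm_min_recomb(aln)
        if 0 < len(pairs) <= 10:
            break
    assert rm == _brute_force_rm(pairs)
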
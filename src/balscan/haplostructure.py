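"""Haplotype structure: distances, NJ trees, branch mapping, recombination.

A neighbor-joining tree over uncorrected pairwise distances summarises how
strains cluster (under long-term balancing selection, deep clusters of
intermediate frequency are expected).  Polymorphic changes are mapped onto
tree branches when their carrier set matches a bipartition exactly; the
four-gamete test with the Hudson–Kaplan interval-removal bound gives the
minimum number of recombination events in the history of the sample.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .codon_counts import NUCS, SiteCall
from .curation import GeneAlignment
from .exceptions import BalscanError


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def pairwise_distances(
    aln: GeneAlignment,
    model: str = "p_distance",
    include_outgroup: bool = False,
) -> tuple[list[str], np.ndarray]:
    """Uncorrected p-distances with pairwise gap removal.

    Each pair is compared over the columns where both sequences carry an
    unambiguous base.  ``model='jc'`` applies the Jukes–Cantor correction.
    """
    if model not in ("p_distance", "jc"):
        raise ValueError(f"unknown model {model!r}")
    rows = list(aln.records)
    if include_outgroup and aln.outgroup is not None:
        rows.append(aln.outgroup)
    ids = [sid for sid, _ in rows]
    if len(rows) < 3:
        raise BalscanError("need at least 3 sequences for a tree")
    mat = np.array([list(seq) for _, seq in rows], dtype="U1")
    valid = np.isin(mat, list(NUCS))
    m = len(rows)
    dist = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            both = valid[i] & valid[j]
            nsites = int(both.sum())
            if nsites == 0:
                raise BalscanError(
                    f"no comparable columns between {ids[i]} and {ids[j]}"
                )
            d = float(((mat[i] != mat[j]) & both).sum()) / nsites
            if model == "jc":
                if d >= 0.75:
                    raise BalscanError(f"distance too large for JC: {ids[i]},{ids[j]}")
                d = -0.75 * np.log(1 - 4 * d / 3)
            dist[i, j] = dist[j, i] = d
    return ids, dist


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    label: Optional[str] = None
    children: list = field(default_factory=list)  # (child, branch_length)

    def leaves(self) -> frozenset:
        if not self.children:
            return frozenset([self.label])
        out = frozenset()
        for child, _ in self.children:
            out |= child.leaves()
        return out

    def newick_part(self, support: Optional[dict] = None) -> str:
        if not self.children:
            return self.label
        inner = ",".join(
            f"{c.newick_part(support)}:{bl:.6f}" for c, bl in self.children
        )
        lbl = ""
        if support is not None:
            side = self.leaves()
            if side in support:
                lbl = f"{support[side]:.0f}"
        return f"({inner}){lbl}"


@dataclass
class Tree:
    """Unrooted NJ tree with bipartitions keyed for branch lookup."""

    root: _Node
    leaf_ids: list[str]
    branch_lengths: dict  # canonical bipartition -> branch length
    support: dict = field(default_factory=dict)  # canonical bipartition -> %
    clamped: list = field(default_factory=list)  # bipartitions clamped to 0

    def canonical(self, side) -> frozenset:
        """Canonical representative of a bipartition: the side not containing
        the alphabetically first leaf (so each split has one key)."""
        side = frozenset(side)
        anchor = min(self.leaf_ids)
        if anchor in side:
            side = frozenset(self.leaf_ids) - side
        return side

    @property
    def bipartitions(self) -> set:
        return set(self.branch_lengths)

    def newick(self) -> str:
        return self.root.newick_part(self._support_by_side()) + ";"

    def _support_by_side(self) -> dict:
        # node.leaves() gives the child side; index support by every side
        out = {}
        for bip, val in self.support.items():
            out[bip] = val
            out[frozenset(self.leaf_ids) - bip] = val
        return out


def nj_tree(dist: np.ndarray, labels: Sequence[str]) -> Tree:
    """Saitou–Nei neighbor joining.

    Q-matrix minimisation with lowest-index tie-breaking; negative branch
    lengths are clamped to zero and recorded in ``tree.clamped``.  The result
    is unrooted: the final join leaves one trifurcating node.
    """
    dist = np.asarray(dist, float)
    m = dist.shape[0]
    if dist.shape != (m, m) or m < 3:
        raise ValueError("need a square matrix over >= 3 taxa")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if (dist < 0).any():
        raise ValueError("distances must be nonnegative")

    nodes = [_Node(label=lab) for lab in labels]
    D = dist.copy()
    active = list(range(m))
    clamped = []

    def clamp(x):
        if x < 0:
            return 0.0, True
        return float(x), False

    while len(active) > 2:
        r = len(active)
        sub = D[np.ix_(active, active)]
        rowsum = sub.sum(axis=1)
        Q = (r - 2) * sub - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-index tie-break: argmin over flattened row-major order
        fi, fj = divmod(int(np.argmin(Q)), r)
        if fi > fj:
            fi, fj = fj, fi
        i, j = active[fi], active[fj]
        dij = D[i, j]
        li = 0.5 * dij + (rowsum[fi] - rowsum[fj]) / (2 * (r - 2))
        lj = dij - li
        li, ci = clamp(li)
        lj, cj = clamp(lj)
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        if ci:
            clamped.append(nodes[i].leaves())
        if cj:
            clamped.append(nodes[j].leaves())
        # distances from the new node
        Dnew = np.zeros(D.shape[0] + 1)
        for idx, kk in enumerate(active):
            if kk in (i, j):
                continue
            Dnew[kk] = 0.5 * (D[i, kk] + D[j, kk] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : D.shape[0] - 1] = Dnew[: D.shape[0] - 1]
        D[: D.shape[0] - 1, -1] = Dnew[: D.shape[0] - 1]
        nodes.append(new)
        active = [kk for kk in active if kk not in (i, j)] + [len(nodes) - 1]

    # join the last two (or, in the degenerate 3-leaf start, the root is the
    # trifurcation created above); connect remaining nodes at a common root
    i, j = active
    dij, _ = clamp(D[i, j])
    root = _Node(children=[(nodes[i], 0.0), (nodes[j], dij)])
    # flatten a child that is itself internal with two children into the root
    # to realise the standard unrooted trifurcation
    a, la = root.children[0]
    if a.children and la == 0.0:
        root = _Node(children=a.children + [(nodes[j], dij)])

    leaf_ids = list(labels)
    tree = Tree(root=root, leaf_ids=leaf_ids, branch_lengths={}, clamped=[])
    all_leaves = frozenset(leaf_ids)

    def collect(node: _Node):
        for child, bl in node.children:
            side = child.leaves()
            if 0 < len(side) < len(all_leaves):
                key = tree.canonical(side)
                # the two edges meeting at the unrooted "root" describe the
                # same split; sum them
                tree.branch_lengths[key] = tree.branch_lengths.get(key, 0.0) + bl
            collect(child)

    collect(root)
    tree.clamped = [tree.canonical(s) for s in clamped]
    return tree


def bootstrap_support(
    aln: GeneAlignment,
    replicates: int = 1000,
    seed: int = 0,
    include_outgroup: bool = False,
) -> Tree:
    """NJ tree with bootstrap support (column resampling, seeded)."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    ids, dist = pairwise_distances(aln, include_outgroup=include_outgroup)
    tree = nj_tree(dist, ids)
    rows = list(aln.records)
    if include_outgroup and aln.outgroup is not None:
        rows.append(aln.outgroup)
    mat = np.array([list(seq) for _, seq in rows], dtype="U1")
    valid = np.isin(mat, list(NUCS))
    L = mat.shape[1]
    m = len(ids)
    rng = np.random.default_rng(seed)
    hits = {bip: 0 for bip in tree.bipartitions}
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        sub = mat[:, cols]
        subvalid = valid[:, cols]
        D = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                both = subvalid[i] & subvalid[j]
                ns = int(both.sum())
                if ns == 0:
                    raise BalscanError(
                        f"bootstrap replicate with no comparable columns: "
                        f"{ids[i]},{ids[j]}"
                    )
                D[i, j] = D[j, i] = float(((sub[i] != sub[j]) & both).sum()) / ns
        rep = nj_tree(D, ids)
        for bip in rep.bipartitions:
            if bip in hits:
                hits[bip] += 1
    tree.support = {bip: 100.0 * h / replicates for bip, h in hits.items()}
    return tree


# ---------------------------------------------------------------------------
# branch mapping
# ---------------------------------------------------------------------------

@dataclass
class BranchMapping:
    assignments: dict  # SiteCall -> canonical bipartition or 'homoplasious'
    branch_tallies: dict  # canonical bipartition -> {nonsyn, syn, complex}
    n_mapped: int
    n_homoplasious: int


_CATEGORY_SHORT = {
    "nonsyn_poly": "nonsyn",
    "syn_poly": "syn",
    "complex": "complex",
}


def map_variants_to_branches(tree: Tree, calls: Sequence[SiteCall]) -> BranchMapping:
    """Place polymorphic changes on branches without homoplasy.

    A call maps to a branch iff its carrier set (or the complement) equals
    that branch's bipartition side; anything else is homoplasious.  Fixed
    differences (outgroup lineage) are not mapped.
    """
    leaves = set(tree.leaf_ids)
    assignments = {}
    tallies = {bip: {"nonsyn": 0, "syn": 0, "complex": 0} for bip in tree.bipartitions}
    n_mapped = n_homo = 0
    for call in calls:
        if not call.is_polymorphic:
            continue
        carriers = set(call.carrier_set)
        if not carriers:
            continue
        if not carriers <= leaves:
            raise BalscanError(
                f"carriers not in tree: {sorted(carriers - leaves)}"
            )
        key = tree.canonical(carriers)
        if key in tallies:
            assignments[call] = key
            tallies[key][_CATEGORY_SHORT[call.category]] += 1
            n_mapped += 1
        else:
            assignments[call] = "homoplasious"
            n_homo += 1
    return BranchMapping(assignments, tallies, n_mapped, n_homo)


# ---------------------------------------------------------------------------
# four-gamete test and Rm
# ---------------------------------------------------------------------------

def rm_min_recomb(aln: GeneAlignment) -> tuple[list, int]:
    """Minimum recombination events by the four-gamete test.

    Biallelic ingroup sites only (tri-allelic sites are skipped); for each
    site pair, strains gapped or ambiguous at either site are dropped before
    collecting gametes (pairwise deletion).  A pair showing all four gametes
    is incompatible; Rm is the Hudson–Kaplan bound — the maximum number of
    pairwise-disjoint open intervals spanned by incompatible pairs, found by
    greedy right-endpoint selection.
    """
    mat = np.array([list(seq) for _, seq in aln.records], dtype="U1")
    valid = np.isin(mat, list(NUCS))
    sites = []
    for col in range(mat.shape[1]):
        bases = set(mat[valid[:, col], col].tolist())
        if len(bases) == 2:
            sites.append(col)
    incompatible = []
    for ai in range(len(sites)):
        for bi in range(ai + 1, len(sites)):
            i, j = sites[ai], sites[bi]
            both = valid[:, i] & valid[:, j]
            gametes = set(zip(mat[both, i].tolist(), mat[both, j].tolist()))
            if len(gametes) == 4:
                incompatible.append((i, j))
    # greedy stabbing of open intervals, provably optimal
    rm = 0
    last_right = -1
    for left, right in sorted(incompatible, key=lambda p: p[1]):
        if left >= last_right:
            rm += 1
            last_right = right
    return incompatible, rm
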
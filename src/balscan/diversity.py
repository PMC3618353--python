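"""Nucleotide diversity, divergence, Tajima's D, and sliding windows.

π is the mean pairwise difference per site among ingroup strains; K is the
mean per-site difference between each ingroup strain and the outgroup.  Both
can be restricted to synonymous or nonsynonymous sites, in which case the
numerators come from classified codon changes (complete codon deletion) and
the denominators are Nei–Gojobori site totals.

Tajima's D contrasts the pairwise estimator of θ with Watterson's
segregating-sites estimator using the standard normalisation

    D = (π̂ − S/a1) / sqrt(e1 S + e2 S(S−1)),

where π̂ is the *unnormalised* mean number of pairwise differences and a1,
a2, b1, b2, c1, c2, e1, e2 are the usual sample-size constants.  Positive D
(excess of intermediate-frequency variants) is the signature expected under
balancing selection; negative D accompanies an excess of rare variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .codon_counts import (
    GENETIC_CODE,
    NUCS,
    SiteCall,
    classify_variants,
    count_syn_nonsyn_sites,
    pathway_fractions,
)
from .curation import GeneAlignment
from .exceptions import BalscanError, UndefinedStatisticError


def harmonic(m: int) -> float:
    """a1(m) = sum_{j=1..m} 1/j."""
    return float(sum(1.0 / j for j in range(1, m + 1)))


def tajima_constants(n: int) -> dict:
    a1 = harmonic(n - 1)
    a2 = float(sum(1.0 / j**2 for j in range(1, n)))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(n: int, S: int, pairwise_mean: float) -> float:
    """Tajima's D from S segregating sites and the unnormalised mean number
    of pairwise differences, for a sample of ``n`` sequences."""
    if n < 2:
        raise BalscanError("Tajima's D needs at least 2 sequences")
    if S <= 0:
        raise UndefinedStatisticError("Tajima's D undefined for S = 0")
    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    return (pairwise_mean - S / k["a1"]) / math.sqrt(var)


@dataclass
class DiversityStats:
    n: int
    S: int
    pi: float
    theta_w: float
    tajima_d: Optional[float]
    site_class: str  # all | synonymous | nonsynonymous
    denominator_sites: float
    pairwise_mean: float  # unnormalised mean pairwise differences


def _ingroup_matrix(aln: GeneAlignment) -> np.ndarray:
    return np.array([list(seq) for _, seq in aln.records], dtype="U1")


def _pairwise_stats(mat: np.ndarray) -> tuple[float, float]:
    """(mean pairwise differences, mean comparable sites), pairwise deletion."""
    n = mat.shape[0]
    valid = np.isin(mat, list(NUCS))
    diffs = 0.0
    sites = 0.0
    npairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            diffs += float(((mat[i] != mat[j]) & both).sum())
            sites += float(both.sum())
            npairs += 1
    return diffs / npairs, sites / npairs


def _class_counts(calls: Sequence[SiteCall], category: str, n: int):
    """(S, unnormalised mean pairwise differences) for one site class."""
    wanted = "syn_poly" if category == "synonymous" else "nonsyn_poly"
    S = 0
    total = 0.0
    npairs = n * (n - 1) / 2.0
    for call in calls:
        if call.category != wanted:
            continue
        S += 1
        i = call.minor_count
        total += i * (n - i) / npairs
    return S, total


def diversity_stats(
    aln: GeneAlignment,
    site_class: str = "all",
    calls: Optional[Sequence[SiteCall]] = None,
    min_n_for_d: int = 4,
) -> DiversityStats:
    """π, Watterson's θ, and Tajima's D for one gene and site class.

    For ``site_class='all'`` segregating sites and pairwise differences are
    computed column-wise with pairwise deletion; for the synonymous and
    nonsynonymous classes they come from the codon classification (complete
    codon deletion), with Nei–Gojobori site totals as denominators.
    Precomputed ``calls`` may be passed to avoid re-classification.
    """
    n = aln.n_strains
    if n < 2:
        raise BalscanError("need at least 2 sequences")
    if site_class == "all":
        mat = _ingroup_matrix(aln)
        valid = np.isin(mat, list(NUCS))
        seg = 0
        for col in range(mat.shape[1]):
            bases = set(mat[valid[:, col], col].tolist())
            if len(bases) > 1:
                seg += 1
        pairwise_mean, denom = _pairwise_stats(mat)
    elif site_class in ("synonymous", "nonsynonymous"):
        if calls is None:
            calls, counts = classify_variants(aln, require_outgroup=False)
            syn_sites, nonsyn_sites = counts.syn_sites, counts.nonsyn_sites
        else:
            syn_sites, nonsyn_sites = count_syn_nonsyn_sites(aln)
        seg, pairwise_mean = _class_counts(calls, site_class, n)
        denom = syn_sites if site_class == "synonymous" else nonsyn_sites
    else:
        raise ValueError(f"unknown site class {site_class!r}")

    pi = pairwise_mean / denom if denom > 0 else 0.0
    a1 = harmonic(n - 1)
    theta_w = seg / (a1 * denom) if denom > 0 else 0.0
    d: Optional[float] = None
    if seg > 0 and n >= min_n_for_d:
        d = tajimas_d(n, seg, pairwise_mean)
    return DiversityStats(
        n=n,
        S=seg,
        pi=pi,
        theta_w=theta_w,
        tajima_d=d,
        site_class=site_class,
        denominator_sites=denom,
        pairwise_mean=pairwise_mean,
    )


def divergence_K(
    aln: GeneAlignment,
    site_class: str = "all",
    jukes_cantor: bool = False,
) -> float:
    """Mean per-site divergence of the ingroup strains from the outgroup.

    Averaged over ingroup strains rather than taken from a consensus.  For
    the synonymous/nonsynonymous classes each strain is compared codon by
    codon against the outgroup with pathway averaging, and the class site
    totals are the denominator.  Uncorrected proportion by default;
    ``jukes_cantor=True`` applies the JC69 correction.
    """
    if aln.outgroup is None:
        raise BalscanError(f"{aln.gene_id}: outgroup required for divergence")
    n = aln.n_strains
    if site_class == "all":
        mat = np.array(
            [list(seq) for _, seq in aln.records] + [list(aln.outgroup[1])],
            dtype="U1",
        )
        valid = np.isin(mat, list(NUCS))
        props = []
        for i in range(n):
            both = valid[i] & valid[n]
            sites = int(both.sum())
            if sites == 0:
                raise BalscanError(
                    f"no comparable sites between {aln.records[i][0]} and outgroup"
                )
            props.append(float(((mat[i] != mat[n]) & both).sum()) / sites)
        k = float(np.mean(props))
    elif site_class in ("synonymous", "nonsynonymous"):
        from .codon_counts import _analyzed_codons

        ids, ing, outg, validcod = _analyzed_codons(aln, require_outgroup=True)
        syn_sites, nonsyn_sites = count_syn_nonsyn_sites(
            aln, np.flatnonzero(validcod).tolist()
        )
        denom = syn_sites if site_class == "synonymous" else nonsyn_sites
        if denom <= 0:
            raise UndefinedStatisticError(f"no {site_class} sites")
        per_strain = np.zeros(n)
        for j in np.flatnonzero(validcod):
            oc = "".join(outg[3 * j : 3 * j + 3])
            for i in range(n):
                sc = "".join(ing[i, 3 * j : 3 * j + 3])
                if sc == oc:
                    continue
                syn_f, non_f = pathway_fractions(sc, oc)
                per_strain[i] += syn_f if site_class == "synonymous" else non_f
        k = float(np.mean(per_strain)) / denom
    else:
        raise ValueError(f"unknown site class {site_class!r}")
    if jukes_cantor:
        if k >= 0.75:
            raise BalscanError("divergence too large for JC correction")
        k = -0.75 * math.log(1.0 - 4.0 * k / 3.0)
    return k


@dataclass
class WindowTrack:
    windows: list  # (start, end, pi, K) in gap-excluded 0-based half-open coords
    window_size: int
    step: int
    n_columns: int  # columns retained after gap exclusion


def sliding_window_pi_k(
    aln: GeneAlignment, window: int = 200, step: int = 50
) -> WindowTrack:
    """Sliding-window π and K over gap-excluded alignment columns.

    Columns containing a gap or ambiguous base in any ingroup strain or the
    outgroup are removed first (complete deletion); windows then slide over
    the retained columns, so every window's denominator is its own length.
    All sites are used (no codon-class restriction).  Coordinates refer to
    the gap-excluded column index.
    """
    if not (window >= step >= 1):
        raise ValueError("need window >= step >= 1")
    rows = [seq for _, seq in aln.records]
    has_out = aln.outgroup is not None
    if has_out:
        rows.append(aln.outgroup[1])
    mat = np.array([list(s) for s in rows], dtype="U1")
    keep = np.isin(mat, list(NUCS)).all(axis=0)
    mat = mat[:, keep]
    n = aln.n_strains
    L = mat.shape[1]
    windows = []
    if window >= L:
        starts = [0]
    else:
        starts = list(range(0, L - window + 1, step))
        if starts[-1] + window < L:
            starts.append(L - window)
    for s in starts:
        e = min(s + window, L)
        sub = mat[:, s:e]
        width = e - s
        diffs = 0.0
        npairs = 0
        for i in range(n):
            for j in range(i + 1, n):
                diffs += float((sub[i] != sub[j]).sum())
                npairs += 1
        pi = (diffs / npairs) / width if npairs else 0.0
        if has_out:
            K = float(np.mean([(sub[i] != sub[n]).sum() for i in range(n)])) / width
        else:
            K = float("nan")
        windows.append((s, e, pi, K))
    return WindowTrack(windows=windows, window_size=window, step=step, n_columns=L)
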
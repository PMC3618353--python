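"""Multilocus HKA tests: classic chi-square and maximum-likelihood variants.

Both tests ask whether loci share a common ratio of within-species
polymorphism to between-species divergence, as expected when all loci evolve
neutrally with locus-specific mutation rates.  Data per locus are S
(segregating synonymous sites), D (synonymous divergence count to one
outgroup sequence), L (synonymous sites surveyed) and n (sample size).

Classic test (method of moments)
    θ̂_i and a shared divergence time T̂ solve
        θ̂_i = (S_i + D_i) / (a(n_i) + T̂ + 1),   Σ D_i = (T̂ + 1) Σ θ̂_i,
    with a(n) = Σ_{j<n} 1/j.  The statistic sums (obs − exp)²/var over both S
    and D at every locus, with Var[S_i] = θ_i a_i + θ_i² b_i
    (b(n) = Σ_{j<n} 1/j²) and Var[D_i] = θ_i (T+1) + θ_i², and is referred to
    a chi-square with (#loci − 1) degrees of freedom.

Maximum-likelihood test
    S_i ~ Poisson(k_i θ_i a(n_i)),   D_i ~ Poisson(θ_i (T + (1 + k_i)/2)),
    where k_i is a per-locus selection scalar (k ≡ 1 at neutral loci; the
    (1+k)/2 term carries the ancestral-polymorphism contribution to
    divergence).  The likelihood is maximised by a seeded log-scale
    random-walk Metropolis search over (θ, T, k) used as a maximiser (best
    visited state), followed by a deterministic quasi-Newton polish.  A
    likelihood-ratio test with df = number of free k parameters compares the
    selection model against the all-neutral null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.special import gammaln
from scipy.stats import chi2

from .exceptions import BalscanError, UndefinedStatisticError


def _a(n: int) -> float:
    return float(sum(1.0 / j for j in range(1, n)))


def _b(n: int) -> float:
    return float(sum(1.0 / j**2 for j in range(1, n)))


@dataclass(frozen=True)
class HkaLocus:
    locus_id: str
    S: int
    D: int
    L: float
    n: int

    def __post_init__(self):
        if self.S < 0 or self.D < 0:
            raise ValueError("S and D must be nonnegative")
        if self.L <= 0:
            raise ValueError("L must be positive")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def locus_summary(aln, calls=None, counts=None) -> HkaLocus:
    """Synonymous-class HKA summary (S, D, L, n) from a curated alignment."""
    from .codon_counts import classify_variants

    if calls is None or counts is None:
        calls, counts = classify_variants(aln)
    S = sum(1 for c in calls if c.category == "syn_poly")
    return HkaLocus(
        locus_id=aln.gene_id, S=S, D=counts.Ds, L=counts.syn_sites, n=counts.n_strains
    )


# ---------------------------------------------------------------------------
# classic chi-square HKA
# ---------------------------------------------------------------------------

def hka_chisq(loci: Sequence[HkaLocus]) -> tuple[float, int, float]:
    """Classic multilocus HKA: (statistic, df, p)."""
    if len(loci) < 2:
        raise ValueError("need at least 2 loci")
    S = np.array([l.S for l in loci], float)
    D = np.array([l.D for l in loci], float)
    a = np.array([_a(l.n) for l in loci])
    b = np.array([_b(l.n) for l in loci])

    def theta_of(T: float) -> np.ndarray:
        return (S + D) / (a + T + 1.0)

    def g(T: float) -> float:
        return float(D.sum() - (T + 1.0) * theta_of(T).sum())

    # g is decreasing in T; bracket the root
    lo, hi = 1e-9, 1.0
    while g(hi) > 0:
        hi *= 2.0
        if hi > 1e9:
            raise BalscanError("HKA moment solver failed to bracket T")
    if g(lo) < 0:
        # all divergence is explainable with T -> 0
        T_hat = lo
    else:
        T_hat = brentq(g, lo, hi, xtol=1e-12, rtol=1e-12)
    theta = theta_of(T_hat)

    ES = theta * a
    ED = theta * (T_hat + 1.0)
    VS = theta * a + theta**2 * b
    VD = theta * (T_hat + 1.0) + theta**2
    stat = float(((S - ES) ** 2 / VS).sum() + ((D - ED) ** 2 / VD).sum())
    df = len(loci) - 1
    p = float(chi2.sf(stat, df))
    return stat, df, p


# ---------------------------------------------------------------------------
# maximum-likelihood HKA
# ---------------------------------------------------------------------------

@dataclass
class HkaFit:
    theta: dict  # locus_id -> fitted per-locus theta
    T: float
    k: dict  # locus_id -> fitted selection scalar (selected loci only)
    lnL: float
    chain_length: int
    seed: int
    accepted_fraction: float


@dataclass
class HkaLrt:
    lnL_null: float
    lnL_alt: float
    statistic: float
    df: int
    p_value: float
    fit_null: Optional[HkaFit] = None
    fit_alt: Optional[HkaFit] = None


def _loglik(S, D, a, theta, T, k) -> float:
    lamS = k * theta * a
    lamD = theta * (T + (1.0 + k) / 2.0)
    if np.any(lamS <= 0) or np.any(lamD <= 0):
        return -np.inf
    return float(
        (S * np.log(lamS) - lamS - gammaln(S + 1)).sum()
        + (D * np.log(lamD) - lamD - gammaln(D + 1)).sum()
    )


def _loglik_factory(S, D, a, nloc, sel_idx):
    """Closure evaluating lnL from the log-parameter vector, with the
    factorial constants precomputed once (this is the Metropolis hot path)."""
    const = float(-(gammaln(S + 1).sum() + gammaln(D + 1).sum()))
    sel = np.asarray(sel_idx, dtype=int)

    def f(xv) -> float:
        theta = np.exp(xv[:nloc])
        T = math.exp(xv[nloc])
        k = np.ones(nloc)
        if sel.size:
            k[sel] = np.exp(xv[nloc + 1 :])
        lamS = k * theta * a
        lamD = theta * (T + (1.0 + k) / 2.0)
        return const + float(
            (S * np.log(lamS) - lamS).sum() + (D * np.log(lamD) - lamD).sum()
        )

    return f


def _null_start(loci: Sequence[HkaLocus]) -> tuple[np.ndarray, float]:
    """Moment estimates as the chain's starting state."""
    S = np.array([l.S for l in loci], float)
    D = np.array([l.D for l in loci], float)
    a = np.array([_a(l.n) for l in loci])

    def g(T):
        return float(D.sum() - (T + 1.0) * ((S + D) / (a + T + 1.0)).sum())

    lo, hi = 1e-6, 1.0
    while g(hi) > 0 and hi < 1e9:
        hi *= 2.0
    try:
        T0 = brentq(g, lo, hi) if g(lo) > 0 else 0.5
    except ValueError:
        T0 = 0.5
    theta0 = (S + D) / (a + T0 + 1.0)
    theta0 = np.maximum(theta0, 1e-6)
    return theta0, max(T0, 1e-3)


def mlhka_fit(
    loci: Sequence[HkaLocus],
    selected: Sequence[str] = (),
    chain_length: int = 100_000,
    seed: int = 0,
    sigma: float = 0.1,
    polish: bool = True,
) -> HkaFit:
    """Maximise the MLHKA likelihood over (θ, T, k_selected).

    One log-scale Gaussian Metropolis step (σ = ``sigma``) per iteration,
    cycling through the coordinates; the returned estimate is the best state
    visited after a 10% burn-in, refined (by default) with L-BFGS in
    log-parameter space.
    """
    ids = [l.locus_id for l in loci]
    unknown = set(selected) - set(ids)
    if unknown:
        raise ValueError(f"selected loci not in input: {sorted(unknown)}")
    for l in loci:
        if l.S == 0 and l.D == 0:
            raise BalscanError(f"locus {l.locus_id}: S = D = 0, uninformative")
    if chain_length < 1000:
        raise ValueError("chain_length must be >= 1000")

    S = np.array([l.S for l in loci], float)
    D = np.array([l.D for l in loci], float)
    a = np.array([_a(l.n) for l in loci])
    nloc = len(loci)
    sel_idx = [ids.index(s) for s in selected]
    nsel = len(sel_idx)

    theta0, T0 = _null_start(loci)
    # params: log theta (nloc), log T, log k (nsel)
    x = np.concatenate([np.log(theta0), [math.log(T0)], np.zeros(nsel)])
    P = x.size

    def unpack(xv):
        theta = np.exp(xv[:nloc])
        T = math.exp(xv[nloc])
        k = np.ones(nloc)
        for j, li in enumerate(sel_idx):
            k[li] = math.exp(xv[nloc + 1 + j])
        return theta, T, k

    f = _loglik_factory(S, D, a, nloc, sel_idx)

    rng = np.random.default_rng(seed)
    cur = f(x)
    if not np.isfinite(cur):
        raise BalscanError("non-finite likelihood at the starting state")
    best_x, best = x.copy(), cur
    burn = chain_length // 10
    accepted = 0
    for it in range(chain_length):
        coord = it % P
        stepsz = sigma * rng.standard_normal()
        xprop = x.copy()
        xprop[coord] += stepsz
        new = f(xprop)
        if new >= cur or rng.random() < math.exp(new - cur):
            x, cur = xprop, new
            accepted += 1
        if it >= burn and cur > best:
            best_x, best = x.copy(), cur

    if polish:
        res = minimize(lambda xv: -f(xv), best_x, method="L-BFGS-B")
        if np.isfinite(res.fun) and -res.fun > best:
            best_x, best = res.x, -float(res.fun)
    if not np.isfinite(best):
        raise BalscanError("MLHKA search produced a non-finite likelihood")

    theta, T, k = unpack(best_x)
    return HkaFit(
        theta={ids[i]: float(theta[i]) for i in range(nloc)},
        T=float(T),
        k={ids[i]: float(k[i]) for i in sel_idx},
        lnL=float(best),
        chain_length=chain_length,
        seed=seed,
        accepted_fraction=accepted / chain_length,
    )


def mlhka_lrt(
    loci: Sequence[HkaLocus],
    selected: Sequence[str],
    chain_length: int = 100_000,
    seeds: int | Sequence[int] = 0,
    keep_fits: bool = False,
) -> HkaLrt:
    """Likelihood-ratio test of free k on ``selected`` loci vs all-neutral.

    ``seeds`` may be a single seed or several; with several, each model is
    fitted once per seed and the best likelihood kept.  The alternative fit
    is additionally polished from the null optimum (k = 1), which guarantees
    lnL_alt >= lnL_null for these nested models.
    """
    if isinstance(seeds, (int, np.integer)):
        seeds = [int(seeds)]
    if not selected:
        null = mlhka_fit(loci, (), chain_length, seeds[0])
        return HkaLrt(null.lnL, null.lnL, 0.0, 0, 1.0,
                      fit_null=null if keep_fits else None,
                      fit_alt=null if keep_fits else None)

    fits_null = [mlhka_fit(loci, (), chain_length, s) for s in seeds]
    fits_alt = [mlhka_fit(loci, selected, chain_length, s) for s in seeds]
    null = max(fits_null, key=lambda fit: fit.lnL)
    alt = max(fits_alt, key=lambda fit: fit.lnL)

    # refine the alternative from the null optimum so nesting holds exactly
    ids = [l.locus_id for l in loci]
    S = np.array([l.S for l in loci], float)
    D = np.array([l.D for l in loci], float)
    a = np.array([_a(l.n) for l in loci])
    nloc = len(loci)
    sel_idx = [ids.index(s) for s in selected]
    f = _loglik_factory(S, D, a, nloc, sel_idx)

    x_null = np.concatenate(
        [np.log([null.theta[i] for i in ids]), [math.log(null.T)],
         np.zeros(len(selected))]
    )
    res = minimize(lambda xv: -f(xv), x_null, method="L-BFGS-B")
    if np.isfinite(res.fun) and -res.fun > alt.lnL:
        xv = res.x
        theta = np.exp(xv[:nloc])
        T = math.exp(xv[nloc])
        alt = HkaFit(
            theta={ids[i]: float(theta[i]) for i in range(nloc)},
            T=float(T),
            k={ids[li]: float(math.exp(xv[nloc + 1 + j]))
               for j, li in enumerate(sel_idx)},
            lnL=-float(res.fun),
            chain_length=chain_length,
            seed=seeds[0],
            accepted_fraction=alt.accepted_fraction,
        )

    stat = 2.0 * (alt.lnL - null.lnL)
    if stat < -1e-6:
        raise BalscanError(
            f"lnL_alt < lnL_null ({alt.lnL:.6f} < {null.lnL:.6f}); "
            "increase chain_length or supply more seeds"
        )
    stat = max(0.0, stat)
    df = len(selected)
    p = float(chi2.sf(stat, df))
    return HkaLrt(null.lnL, alt.lnL, stat, df, p,
                  fit_null=null if keep_fits else None,
                  fit_alt=alt if keep_fits else None)


# ---------------------------------------------------------------------------
# TSV I/O for locus summaries
# ---------------------------------------------------------------------------

def read_loci_tsv(path) -> list[HkaLocus]:
    loci = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            loci.append(
                HkaLocus(
                    locus_id=parts[idx["locus"]],
                    S=int(parts[idx["S"]]),
                    D=int(parts[idx["D"]]),
                    L=float(parts[idx["L"]]),
                    n=int(parts[idx["n"]]),
                )
            )
    return loci


def write_loci_tsv(loci: Sequence[HkaLocus], path) -> None:
    with open(path, "w") as fh:
        fh.write("locus\tS\tD\tL\tn\n")
        for l in loci:
            fh.write(f"{l.locus_id}\t{l.S}\t{l.D}\t{l.L:.6g}\t{l.n}\n")
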
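# Methods

`balscan` implements the classical polymorphism/divergence battery used to
detect balancing selection in coding genes of a largely selfing yeast
population, together with a synthetic-data generator that reproduces the
statistical structure those tests assume. This note records the models, the
conventions and numerical choices, and what the synthetic data do and do not
emulate.

## Alignment curation

Input is a gapped FASTA alignment of one gene's coding region: ingroup
strains (one of which is the S288C-style reference) and optionally one
outgroup sequence. Four deterministic cleanup rules are applied, in a fixed
order (length → internal stop → unique insertion → ambiguity):

1. **Length rule.** An ingroup strain is dropped when its ungapped length is
   below `min_length_fraction` × the ungapped reference length (0.99 for
   control genes, 0.90 for candidate genes, the laxer cutoff accommodating
   very long genes with partial coverage). "Length" is the ungapped
   nucleotide count: the rule compares sequences, not alignment rows.
2. **Internal stop codons.** A strain with a stop codon in the reference
   frame anywhere before the terminal codon is dropped.
3. **Unique insertions.** A base present in exactly one retained record at a
   column gapped in all other records (reference and outgroup included) is
   treated as a sequencing error: the base is removed and the column deleted.
4. **Heterozygous base calls.** Two-nucleotide IUPAC codes are resolved by a
   uniform choice between the two encoded nucleotides from one seeded
   generator, consumed in record order then column order, so the outcome is
   reproducible and independent of file-system ordering. Codes encoding
   three or four nucleotides become `N` (the curated data only ever contain
   two-allele heterozygotes; anything else is treated as missing).

Every action is logged (strain, action, column, detail); curation is
idempotent, and the order of the rules is a convention of this package (the
source protocol does not fix one). The reference frame — reference-base
columns taken three at a time — defines codon coordinates for everything
downstream; columns where the reference is gapped are excluded from codon
analyses, and a terminal reference stop codon is dropped from analysis.

## Codon classification and the MK table

For each codon passing **complete deletion** (no gap or `N` in any retained
strain or the outgroup — this makes counts order-independent), variation is
decomposed into single-nucleotide changes:

* a position variable within the ingroup is a **polymorphism**; a position
  monomorphic in the ingroup but different from the outgroup is a **fixed
  difference**. A site both polymorphic and different from the outgroup
  counts as polymorphic only — no double counting toward divergence.
* each change is **synonymous** or **nonsynonymous** by translating the two
  codons in context. Codons with several changed positions are handled with
  the Nei–Gojobori pathway convention: all orderings of the single-base
  steps are enumerated, orderings passing through an intermediate stop codon
  are discarded, and the syn/nonsyn fractions are averaged over the rest
  (if every ordering is blocked, all are used). Divergence tallies therefore
  accumulate as fractions and are rounded only at reporting time; the exact
  accumulators are kept alongside (`dn_exact`, `ds_exact`).
* ingroup polymorphism at two or more codon positions is decomposed position
  by position when the positions vary independently (the observed codons
  form the Cartesian product of the per-position alleles, evaluated in the
  majority-codon context); otherwise the codon is **complex** — reported,
  mapped on trees, but excluded from the MK tallies.
* tri-allelic positions count as one polymorphic site, classed by the
  majority of the single-step changes from the major allele, ties broken
  toward synonymous.

Site totals follow Nei–Gojobori: each position of each codon contributes the
fraction of its nine single-nucleotide changes that are synonymous, averaged
over the ingroup strains; changes to stop codons count on the nonsynonymous
side, so each codon contributes exactly 3 sites. The denominators for
per-site rates (π_syn, K_syn) use these totals.

The MK test is a two-tailed Fisher exact test on [[Pn, Ps], [Dn, Ds]] using
the point-probability rule (sum of all tables with the observed margins
whose probability does not exceed the observed table's); a tail-doubling
variant is available behind a flag. Bonferroni adjustment multiplies by the
number of genes tested in the set, capped at 1. The neutrality index is
NI = (Pn/Ps)/(Dn/Ds); across a gene set the ratio-of-weighted-sums form

    NI_w = Σ_i[Ds_i·Pn_i/(Ps_i+Ds_i)] / Σ_i[Ps_i·Dn_i/(Ps_i+Ds_i)]

avoids the small-count bias of averaging per-gene ratios. The
excess-nonsynonymous statistic Pn − Ps·(Dn/Ds) is reported unclamped.

Synonymous changes are additionally tallied by the codon-preference class of
the derived codon (polymorphisms polarized by the outgroup; fixed
differences attributed to the ingroup lineage — the standard single-outgroup
convention, stated rather than hidden). The default preference table is the
standard *S. cerevisiae* optimal-codon set; it is an input, not a constant.

## Diversity, Tajima's D, windows

π is the mean pairwise difference per site (pairwise deletion for the
all-sites class; for the synonymous/nonsynonymous classes the numerator
comes from the classified calls under complete codon deletion and the
denominator is the corresponding Nei–Gojobori site total). Watterson's
θ_W = S/(a₁·sites) with a₁ = Σ_{j<n} 1/j. Tajima's D uses segregating-site
counts and **unnormalised** mean pairwise differences with the standard
a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ constants; it is undefined (returned as
`None`, never 0) when S = 0 or n < 4 (configurable). Divergence K is
averaged over ingroup strains against the outgroup — not computed from a
consensus — with pathway-averaged codon comparisons for the class-restricted
versions and an optional Jukes–Cantor correction.

The sliding-window track (defaults 200 bp window, 50 bp step) first removes
every column with a gap or ambiguous base in any sequence (complete
deletion), then slides over the retained columns; window coordinates refer
to the gap-excluded column index and each window's denominator is its own
width. All sites are used, with no codon-class restriction.

## HKA tests

Per-locus inputs are the synonymous-class summaries (S segregating
synonymous sites, D synonymous divergence, L synonymous sites, n strains).

**Classic test.** Method-of-moments under neutral equilibrium with one
outgroup sequence: θ̂_i = (S_i+D_i)/(a(n_i)+T̂+1) with T̂ solving
Σ D_i = (T̂+1) Σ θ̂_i (1-D Brent root find; the moment equations then hold
exactly per locus). The statistic sums (obs−exp)²/var over S and D with
Var[S_i] = θ_i a_i + θ_i² b_i (b = Σ 1/j²) and Var[D_i] = θ_i(T+1) + θ_i²,
referred to χ² with (#loci − 1) degrees of freedom.

**Maximum-likelihood test.** S_i ~ Poisson(k_i θ_i a(n_i)) and
D_i ~ Poisson(θ_i (T + (1+k_i)/2)), with k ≡ 1 at neutral loci; the
(1+k)/2 term carries ancestral polymorphism into divergence. The likelihood
is maximised by a seeded log-scale random-walk Metropolis search (Gaussian
σ = 0.1 steps, one coordinate per iteration cycled over log θ, log T, log k;
10% burn-in; best visited state retained — the chain is a maximiser, not a
posterior sampler; default chain length 100,000). A deterministic L-BFGS
polish from the best state follows: at practical chain lengths the raw
best-state estimate carries Monte-Carlo noise of the same order as small
likelihood-ratio statistics, and the polish removes it while preserving the
specified search. For the likelihood-ratio test (df = number of free k) the
alternative model is additionally polished from the null optimum, which
makes lnL_alt ≥ lnL_null hold structurally for these nested models. The
null fit agrees with the classic moment estimates (exactly, for this
Poisson system — verified in the tests). Loci with S = D = 0 are rejected
as uninformative.

## Trees, branch mapping, recombination

Distances are uncorrected p-distances with pairwise gap removal (JC69
behind a flag). Neighbor joining follows Saitou–Nei with Q-matrix
minimisation, lowest-index tie-breaking, and negative branch lengths clamped
to zero (recorded). Bootstrap resamples nucleotide columns with replacement
(default 1000 replicates, seeded); support is the percentage of replicates
containing each original bipartition. A polymorphic change maps to a branch
iff its carrier set (or complement) equals the branch's bipartition side;
anything else is homoplasious, and mapped + homoplasious counts always sum
to the total. The four-gamete test uses biallelic sites only (tri-allelic
sites skipped), with per-pair deletion of gapped strains; Rm is the
Hudson–Kaplan bound computed by greedy right-endpoint selection over the
open intervals between incompatible site pairs (provably optimal for
interval stabbing, and checked against exhaustion in the tests).

## Linked-diversity theory

Diversity at distance d bp from a balanced polymorphism, relative to an
unlinked neutral locus, is 1 + 1/(4·N·r_bp·d·(1−F)). When F is not given it
derives from the outcrossing rate o at the partial-selfing equilibrium
F = (1−o)/(1+o), so 1−F = 2o/(1+o) ≈ 4×10⁻⁵ at o = 2×10⁻⁵. With the yeast
parameters (N = 1.6×10⁷, r = 3.5×10⁻⁶/bp/gen) the direct evaluation gives a
9.59-fold elevation at 13 bp and 1.99-fold at 113 bp — i.e. the published
round numbers (10-fold at ~13 bp, 2-fold at ~113 bp) are reproduced within
rounding, and exactly inverting the formula gives 12.4 bp and 111.6 bp; no
choice of F convention reproduces the printed distances exactly, so parity
here is a within-rounding property, not an equality.

## The synthetic-data generator

Loci are built infinite-sites style on a random sense-codon scaffold: at
most one mutation per codon, no back-mutation, so every generated event is
recovered exactly by the classifier and all expectations are closed-form.
Segregating variants arrive as Poisson(k·θ·a(n)) per class with derived
counts i ∝ 1/i (the neutral frequency law); the outgroup lineage receives
Poisson(θ·(T + (1+k)/2)) substitutions per class on separate codons, so
polymorphism and divergence are disjoint by construction and the divergence
model matches the ML-HKA likelihood exactly. Three mechanisms are available:

* **deleterious excess** — nonsynonymous variants are forced to singletons
  with probability `rare_bias` (default 0.6), and `nonsyn_fixation` scales
  nonsynonymous divergence only (deleterious variants segregate but do not
  fix), producing the MK-significant / HKA-silent pattern;
* **balanced** — the sample splits into 2–3 groups and each group stem
  receives Poisson(τ) extra variants per class (intermediate frequencies,
  deep structure), while k > 1 elevates the polymorphism rate, producing
  the MK-significant / HKA-significant pattern with positive Tajima's D;
* **neutral** — neither mechanism.

Default study conditions used in the calibration tests and analysis
scripts: n = 20 strains; control loci of 200–250 codons with θ_syn = 6,
θ_nonsyn = 3 (a 2:1 site ratio, roughly the coding-sequence norm) and
T_div = 3; the balanced mimic uses k = 4, groups (7,7,6) with stem rates
(2 syn, 4 nonsyn) and nonsyn_fixation = 0.25; deleterious mimics use
θ_nonsyn = 12 with nonsyn_fixation = 0.25. These produce MK tables and π/K
contrasts on the scale of the published candidate genes.

What the generator does **not** emulate: genealogical linkage between sites
(carrier sets are independent across sites, i.e. effectively free
recombination — so four-gamete counts on simulated loci are large by
construction and Rm correctness is tested on hand-built fixtures and
exhaustive oracles instead); recurrent or back mutation; rate heterogeneity
along the gene; and base-composition/codon-usage realism. Passing
calibration therefore demonstrates correctness of the statistics under the
stated sampling models, not robustness to real-data linkage structure.

## Calibration scales

The acceptance tests run: 500 neutral replicates (n = 20, 300 codons) for
the MK type-I rate (bound: 5% plus binomial sampling slack) and Tajima's D
centering (|mean| < 0.2); 300 replicates of an 11-locus MLHKA LRT at chain
length 20,000 (type-I ≤ 7% at nominal 5%); 20 seeds of k-recovery at true
k = 5 (median k̂ within [3, 8]; detection > 50%); and 40 replicates of the
balanced-vs-deleterious discrimination (each pattern must hold in the
majority). These replicate counts are the package's chosen calibration
scale; the statistics themselves are size-independent.

## Numerical conventions

Coordinates are 0-based half-open internally and 1-based inclusive in
human-readable reports. Undefined statistics raise or return `None` — never
0. Fractional divergence tallies round half-to-even at reporting. Seeds are
mandatory wherever randomness enters (curation of heterozygotes, MCMC,
bootstrap, simulation); multi-locus runs derive independent child seeds from
one master seed via a seed sequence, so results are independent of
evaluation order. Ties in NJ's Q-matrix go to the lowest index pair; ties in
majority-codon choices go to the lexicographically smallest codon.

## Known limitations

Exact parity with legacy implementations of the synonymous/nonsynonymous
conventions is not guaranteed at every codon (deletion policy and multi-hit
handling differ across tools); the published per-gene counts are reproduced
from the printed tables, and reproduction from the original supplementary
alignments is encoded as a test that requires that external dataset to be
supplied. The ML-HKA likelihood here is the standard Poisson form; the
original program's exact treatment of ancestral polymorphism is not
published, so p-values may differ in the tails. The preferred-codon tally
depends on the preference table chosen; no published table accompanies the
source counts.
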
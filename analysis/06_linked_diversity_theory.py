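#!/usr/bin/env python
"""Expected footprint of balancing selection on linked neutral diversity.

Evaluates the 1 + 1/[4 N r d (1-F)] elevation factor with the yeast
parameters (N = 1.6e7, r = 3.5e-6 per bp per generation, outcrossing rate
2e-5 per generation, so 1-F ~ 4e-5) over a range of distances, and the
distances at which 10-fold and 2-fold elevations are expected — the reason
balancing selection leaves only a very narrow footprint in a mostly selfing
genome with high recombination.
"""

from common import results_path

from balscan.theory import TheoryParams, distance_for_factor, relative_diversity_factor

PARAMS = TheoryParams(N=1.6e7, r_bp=3.5e-6, o=2e-5)


def main():
    with open(results_path("linked_diversity.tsv"), "w") as fh:
        fh.write("distance_bp\tfactor\n")
        for d in (1, 5, 13, 25, 50, 113, 250, 500, 1000, 5000):
            fh.write(f"{d}\t{relative_diversity_factor(d, PARAMS):.3f}\n")
    f13 = relative_diversity_factor(13, PARAMS)
    f113 = relative_diversity_factor(113, PARAMS)
    d10 = distance_for_factor(10, PARAMS)
    d2 = distance_for_factor(2, PARAMS)
    print(f"1-F = {PARAMS.one_minus_F:.3g} (from outcrossing 2e-5)")
    print(f"elevation factor: {f13:.2f} at 13 bp, {f113:.2f} at 113 bp")
    print(f"10-fold elevation within {d10:.1f} bp; 2-fold within {d2:.1f} bp")
    print("-> results/linked_diversity.tsv")


if __name__ == "__main__":
    main()
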
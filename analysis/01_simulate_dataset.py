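#!/usr/bin/env python
"""Generate the synthetic study dataset and record its truth manifest.

21 neutral control loci plus 5 candidate loci (4 deleterious-excess mimics,
1 balanced mimic with 3-group haplotype structure), all with 20 ingroup
strains and one outgroup.  Writes the truth manifest and a per-locus summary;
the alignments themselves are regenerated on demand by the later scripts
(deterministic under the master seed), so they are not stored.
"""

import json

from common import build_dataset, results_path


def main():
    alns, manifest = build_dataset()
    with open(results_path("sim_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")
    with open(results_path("sim_dataset_summary.tsv"), "w") as fh:
        fh.write("gene\trole\tmode\tn\tcodons\ttheta_syn\ttheta_nonsyn\tk\n")
        for m in manifest:
            fh.write(
                f"{m['gene_id']}\t{m['role']}\t{m['mode']}\t{m['n']}\t"
                f"{m['L']}\t{m['theta_syn']}\t{m['theta_nonsyn']}\t{m['k']}\n"
            )
    n_ctrl = sum(1 for m in manifest if m["role"] == "control")
    n_test = len(manifest) - n_ctrl
    print(f"simulated {n_ctrl} control + {n_test} candidate loci "
          f"(one balanced mimic: t04); manifest -> results/sim_manifest.json")


if __name__ == "__main__":
    main()
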
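"""Shared study definition for the analysis scripts.

The synthetic study mirrors the published design: 21 neutral control genes
and 5 candidate genes that all show an excess of nonsynonymous polymorphism
by the MK test, of which exactly one (the ZRT1 mimic, ``t04``) owes its
excess to balancing selection — deep 3-group haplotype structure, elevated
synonymous polymorphism (k = 4), and strong constraint on nonsynonymous
fixation — while the other four are deleterious-excess mimics (inflated
nonsynonymous polymorphism biased toward singletons, normal synonymous
variation).  All loci share n = 20 strains and a divergence depth matching
the *S. cerevisiae*/*S. paradoxus* contrast scale used throughout.

Every script regenerates the dataset deterministically from MASTER_SEED, so
no alignment files need to be stored.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from balscan.simdata import SimConfig, simulate_dataset  # noqa: E402

MASTER_SEED = 2013
RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")

BALANCED_GENE = "t04"

CONTROL = SimConfig(n=20, L=250, theta_syn=6.0, theta_nonsyn=3.0, T_div=3.0)

DELETERIOUS = SimConfig(
    n=20, L=300, theta_syn=6.0, theta_nonsyn=12.0, T_div=3.0,
    mode="deleterious_excess", rare_bias=0.6, nonsyn_fixation=0.25,
)

BALANCED = SimConfig(
    n=20, L=400, theta_syn=6.0, theta_nonsyn=3.0, T_div=3.0,
    mode="balanced", groups=([7, 7, 6], (2.0, 4.0)),
    k=4.0, nonsyn_fixation=0.25,
)


def build_dataset():
    controls = [CONTROL] * 21
    candidates = [DELETERIOUS] * 4 + [BALANCED]
    alns, manifest = simulate_dataset(controls, candidates, seed=MASTER_SEED)
    return alns, manifest


def results_path(name: str) -> str:
    os.makedirs(RESULTS, exist_ok=True)
    return os.path.join(RESULTS, name)
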
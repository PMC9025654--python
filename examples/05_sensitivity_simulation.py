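"""Why a smaller database identifies more peptides at the same FDR.

A minimal target-decoy simulation: each spectrum's true match competes
with random matches whose number grows with database size.  More
competition raises decoy scores, pushes the FDR cutoff up, and loses true
identifications — the mechanism the targeted database exploits.
"""

import numpy as np

from introspect import SimConfig, SizedPeptideSet, simulate_two_round_gain
from introspect.synthetic import random_peptides

true_peptides = random_peptides(500, seed=3)
full = SizedPeptideSet(true_peptides, 1_000_000)
targeted = SizedPeptideSet(true_peptides, 10_000)

ids_full, ids_targeted = [], []
for s in range(10):
    res = simulate_two_round_gain(
        true_peptides, full, targeted, SimConfig(n_true_spectra=2000, rng_seed=s)
    )
    ids_full.append(res.ids_full)
    ids_targeted.append(res.ids_targeted)

print(f"mean identifications at 1% FDR, full database (1e6):     {np.mean(ids_full):6.1f}")
print(f"mean identifications at 1% FDR, targeted database (1e4): {np.mean(ids_targeted):6.1f}")
print(
    "\nSame spectra, same true peptides: only the amount of random-match\n"
    "competition differs. The targeted database recovers far more true\n"
    "peptides under the identical 1% FDR control."
)
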
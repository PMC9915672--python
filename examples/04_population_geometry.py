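"""Separation angles and vector lengths between sound-level representations.

The mean population vector for each sound level is compared across levels:
angles (silence-referenced) measure identity-based separation, lengths
measure magnitude-based separation.
"""

import numpy as np

from popcode.geometry import angle_matrix_from_table, length_matrix_from_table
from popcode.synth import SynthConfig, generate_population

_, table = generate_population(SynthConfig(n_neurons=200, seed=7, activated="sst"))
iu = np.triu_indices(6, k=1)  # unordered pairs of the 6 nonzero levels

for laser in ("none", "high"):
    levels, ang = angle_matrix_from_table(table, laser)
    _, length = length_matrix_from_table(table, laser)
    print(
        f"laser={laser:6s} mean pair angle {np.nanmean(ang[iu]):6.2f} deg, "
        f"mean pair length {np.nanmean(length[iu]):6.2f} a.u."
    )

print(
    "\nWith SST-like activation the angles between level representations widen"
    "\nwhile the vectors shorten: the code separates identities, not magnitudes."
)
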
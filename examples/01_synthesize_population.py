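"""Generate a synthetic population and its trial-level response table.

Each neuron is monotonic (sigmoid tuning) or nonmonotonic (Gaussian tuning);
laser conditions shift tuning parameters the way SST-interneuron activation
does in the recorded populations.
"""

import numpy as np

from popcode.synth import SynthConfig, generate_population

cfg = SynthConfig(n_neurons=20, frac_monotonic=0.5, activated="sst", seed=0)
truth, table = generate_population(cfg)

kinds, counts = np.unique(truth.kinds, return_counts=True)
print(f"{cfg.n_neurons} neurons: " + ", ".join(f"{c} {k}" for k, c in zip(kinds, counts)))
print(f"table: {len(table)} rows = neurons x 7 levels x 3 lasers x {cfg.n_trials} trials")
print("\nmean response at 90 dB by laser (dF/Fstd):")
print(table[table.level_db == 90].groupby("laser")["response"].mean().round(3).to_string())
print(
    "\nUnder SST-like activation the high-laser responses at 90 dB drop:"
    "\nmonotonic midpoints shift up and nonmonotonic amplitudes shrink."
)
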
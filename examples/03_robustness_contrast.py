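"""Parsimony versus robustness: blind mass deletion vs the fragile skeleton.

The fully connected net shrugs off random removal of 95% of its links in
most trials, while the minimal skeleton produced by guided pruning dies if
any single one of its links is deleted.
"""

import numpy as np

import attractorprune as ap

n = 100
streams, _ = ap.seed_streams(33, ["attractor", "trials", "probes"])
s = ap.random_attractor(n, streams["attractor"])
w = ap.outer_attractor_matrix(s)

best, survivals = ap.mass_elimination_sweep(
    w, s, streams["trials"], n_trials=20, n_starts=100
)
for pct, surv in survivals.items():
    print(f"remove {pct:.0f}% of {n * n} links blindly: "
          f"attractor retained in {surv:.0%} of 20 trials")
print(f"largest removal with majority survival: {best:.0f}%")

res = ap.single_attractor_experiment(n, seed=33)
tstar, s2 = res["tstar"], res["s"]
fatal = 0
links = np.flatnonzero(tstar)
for idx in links:
    trial = tstar.copy()
    trial.flat[idx] = 0
    retained, _ = ap.retention_test(trial, s2, n_starts=100, rng=streams["probes"])
    fatal += int(not retained)
print(f"minimal skeleton ({len(links)} links): deleting any single link is "
      f"fatal in {fatal}/{len(links)} cases")
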
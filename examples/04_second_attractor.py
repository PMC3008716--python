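"""How much connectivity does a second attractor need?

Grafts a second pattern r (orthogonal to s) onto the minimal skeleton via
the two-pattern Hebbian rule U_ij = s_i s_j + r_i r_j on all non-skeleton
entries, then prunes the added links while protecting the skeleton.  The
fraction of random starts captured by ±r falls from about one half toward
zero as links are removed, and below roughly two links per node the second
pattern stops being a fixed point at all.
"""

import pandas as pd

import attractorprune as ap

n = 50
single = ap.single_attractor_experiment(n, seed=11)
dual = ap.dual_attractor_experiment(single["tstar"], single["s"], seed=21)
trace = dual["trace"]

print(f"skeleton: {ap.count_links(single['tstar'])} protected links; "
      f"two-pattern graft has {ap.count_links(dual['u_full'])} links, "
      f"bulk-pruned to {ap.count_links(dual['u_bulk'])}")

acc = trace.accepted_steps
frame = pd.DataFrame({
    "links_per_node": [s.links_per_node for s in acc],
    "fraction_to_second": [s.fraction_to_second for s in acc],
})
for lo, hi in [(14, 15.1), (7.5, 8.5), (4.5, 5.5), (2.5, 3.5), (1.0, 2.0)]:
    band = frame[(frame.links_per_node >= lo) & (frame.links_per_node < hi)]
    if len(band):
        print(f"  {lo:>4.1f}-{hi:.1f} links/node: "
              f"{band.fraction_to_second.mean():.3f} of 200 probes reach ±r")

print(f"second attractor no longer a fixed point below "
      f"{trace.second_loss_links_per_node:.2f} links per node "
      f"(final net: {dual['final_links']} links)")
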
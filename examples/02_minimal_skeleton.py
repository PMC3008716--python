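"""Prune a single-attractor net down to its minimal supporting skeleton.

Runs the full experiment at N = 50: bulk-prune the 2500-link net to 10
links per node, then delete links one at a time, accepting a deletion only
when the attractor pair {s, -s} stays fixed and 100 fresh random probes
all converge to it.  The run terminates when no single remaining link can
be removed, leaving barely more than one link per node.
"""

import numpy as np

import attractorprune as ap
from attractorprune import metrics

n = 50
res = ap.single_attractor_experiment(n, seed=11)
trace = res["trace"]
tstar = res["tstar"]

print(f"N={n}: started from {n * n} links, bulk-pruned to "
      f"{ap.count_links(res['t_bulk'])}, minimal skeleton has "
      f"{res['final_links']} links ({res['final_links'] / n:.2f} per node)")

received = ap.received_link_counts(tstar)
print(f"incoming links per node: min {received.min()}, max {received.max()}")
print(f"degree histogram (in+out, self once): {ap.degree_histogram(tstar)}")

curve = metrics.normalized_iterations(trace, n)
lo = curve[curve.links_per_node < 2.0]["mean_iterations"].mean()
hi = curve[curve.links_per_node > 6.0]["mean_iterations"].mean()
print(f"mean iterations to converge: {hi:.1f} above 6 links/node vs "
      f"{lo:.1f} below 2 links/node -- sparsity costs speed")
print(f"(accept/reject steps recorded: {len(trace.steps)}, "
      f"accepted: {len(trace.accepted_steps)})")
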
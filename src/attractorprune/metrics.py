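"""Post-processing of pruning runs: degrees, convergence curves, aggregation.

Conventions follow the experiments: a node's degree counts its nonzero
incoming plus outgoing links, with a self-link counted once; links per
node is the total count of nonzero directed entries divided by N; and
cross-size comparison of convergence-speed curves divides mean iterations
by ln(N), the empirical scaling under which the curves for different N
collapse onto one another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pruning import PruneTrace, count_links

__all__ = [
    "RunSummary",
    "degree_histogram",
    "received_link_counts",
    "links_per_node",
    "normalized_iterations",
    "trace_frame",
    "dual_trace_frame",
    "summarize_run",
    "aggregate_runs",
]

#: Common links-per-node grid for cross-N curve comparison (bin width 0.25).
DEFAULT_BINS = np.arange(1.0, 10.0 + 0.25, 0.25)


def links_per_node(w: np.ndarray) -> float:
    return count_links(w) / w.shape[0]


def received_link_counts(w: np.ndarray) -> np.ndarray:
    """Incoming links per node: nonzero entries in each receiving row."""
    return np.count_nonzero(np.asarray(w), axis=1)


def degree_histogram(w: np.ndarray) -> dict[int, int]:
    """Node count per degree, degree = arriving + leaving links, self once."""
    w = np.asarray(w)
    nz = w != 0
    degree = nz.sum(axis=1) + nz.sum(axis=0) - np.diag(nz).astype(np.int64)
    values, counts = np.unique(degree, return_counts=True)
    return {int(d): int(c) for d, c in zip(values, counts)}


def trace_frame(trace: PruneTrace) -> pd.DataFrame:
    """Pruning trace as a tidy frame (one row per attempted deletion)."""
    return pd.DataFrame(
        {
            "step": np.arange(len(trace.steps)),
            "links_remaining": [s.links_remaining for s in trace.steps],
            "links_per_node": [s.links_per_node for s in trace.steps],
            "accepted": [s.accepted for s in trace.steps],
            "mean_iterations": [s.mean_iterations for s in trace.steps],
        }
    )


def dual_trace_frame(trace) -> pd.DataFrame:
    """Dual-pruning trace as a tidy frame, with capture-fraction columns."""
    return pd.DataFrame(
        {
            "step": np.arange(len(trace.steps)),
            "links_remaining": [s.links_remaining for s in trace.steps],
            "links_per_node": [s.links_per_node for s in trace.steps],
            "accepted": [s.accepted for s in trace.steps],
            "mean_iterations": [s.mean_iterations for s in trace.steps],
            "fraction_to_second": [s.fraction_to_second for s in trace.steps],
            "second_is_fixed_point": [s.second_is_fixed_point for s in trace.steps],
            "phase": [s.phase for s in trace.steps],
        }
    )


def normalized_iterations(
    trace: PruneTrace,
    n_nodes: int,
    bins: np.ndarray = DEFAULT_BINS,
) -> pd.DataFrame:
    """Binned convergence-speed curve with the ln(N) normalization.

    Accepted steps are binned on the common links-per-node grid; each bin
    reports the mean of the per-step mean iteration counts and that mean
    divided by ln(N).  Bins without data are dropped.
    """
    if n_nodes < 3:
        raise ValueError("ln(N) normalization needs N >= 3")
    accepted = [s for s in trace.steps if s.accepted and not math.isnan(s.mean_iterations)]
    frame = pd.DataFrame(
        {
            "links_per_node": [s.links_per_node for s in accepted],
            "mean_iterations": [s.mean_iterations for s in accepted],
        }
    )
    frame["bin"] = pd.cut(frame["links_per_node"], bins=bins, labels=False)
    grouped = frame.dropna(subset=["bin"]).groupby("bin")["mean_iterations"].mean()
    centers = (bins[:-1] + bins[1:]) / 2
    out = pd.DataFrame(
        {
            "links_per_node": centers[grouped.index.astype(int)],
            "mean_iterations": grouped.to_numpy(),
        }
    )
    out["normalized_iterations"] = out["mean_iterations"] / math.log(n_nodes)
    return out.reset_index(drop=True)


@dataclass
class RunSummary:
    """Per-run report consumed by :func:`aggregate_runs`."""

    n_nodes: int
    final_links: int
    degree_histogram: dict[int, int]
    iterations_curve: pd.DataFrame
    capture_curve: pd.DataFrame | None = None


def summarize_run(trace: PruneTrace, capture_curve: pd.DataFrame | None = None) -> RunSummary:
    w = trace.final_network
    if w is None:
        raise ValueError("trace has no final network (run incomplete)")
    hist = degree_histogram(w)
    assert sum(hist.values()) == trace.n_nodes, "degree histogram lost nodes"
    return RunSummary(
        n_nodes=trace.n_nodes,
        final_links=count_links(w),
        degree_histogram=hist,
        iterations_curve=normalized_iterations(trace, trace.n_nodes),
        capture_curve=capture_curve,
    )


def aggregate_runs(summaries: list[RunSummary]) -> dict:
    """Pool same-N runs: per-degree mean ± SE, link-count range, mean curves."""
    if not summaries:
        raise ValueError("need at least one run summary")
    sizes = {s.n_nodes for s in summaries}
    if len(sizes) != 1:
        raise ValueError(f"cannot aggregate runs with mixed N: {sorted(sizes)}")
    n_runs = len(summaries)
    degrees = sorted({d for s in summaries for d in s.degree_histogram})
    counts = np.array(
        [[s.degree_histogram.get(d, 0) for d in degrees] for s in summaries],
        dtype=float,
    )
    mean = counts.mean(axis=0)
    se = (
        counts.std(axis=0, ddof=1) / math.sqrt(n_runs)
        if n_runs > 1
        else np.zeros(len(degrees))
    )
    hist = pd.DataFrame({"degree": degrees, "mean_count": mean, "se_count": se})

    final_links = np.array([s.final_links for s in summaries])
    curves = pd.concat([s.iterations_curve for s in summaries], ignore_index=True)
    pooled_curve = (
        curves.groupby("links_per_node", as_index=False)[
            ["mean_iterations", "normalized_iterations"]
        ].mean()
    )
    return {
        "n_nodes": summaries[0].n_nodes,
        "n_runs": n_runs,
        "final_links_mean": float(final_links.mean()),
        "final_links_min": int(final_links.min()),
        "final_links_max": int(final_links.max()),
        "degree_histogram": hist,
        "iterations_curve": pooled_curve,
    }
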
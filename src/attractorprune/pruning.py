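"""Reduction of a single-attractor net to its minimal supporting skeleton.

The experiment starts from the fully connected Hebbian matrix T = s sᵀ,
removes the bulk of the links at random down to ~10 links per node, and
then deletes links one at a time.  Each candidate deletion must survive a
Monte-Carlo *retention test*: the designated attractor pair {s, −s} must
remain fixed, and a fresh panel of random probe states must all reach one
of the two (see :func:`retention_test` for why the complement is part of
the criterion).  When
every remaining link has been tried and rejected since the last accepted
removal, the net is the minimal skeleton T*: deleting any single further
link breaks global convergence (as witnessed by a failing probe).

Retention treats −s as equivalent to s throughout.  Roughly half of all
random starts of the symmetric net provably flow to −s, so global
convergence "to the designated attractor" is only satisfiable under this
complement identification; which of the two a probe reached is still
available from the probe reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import netgen
from .dynamics import probe_basins

__all__ = [
    "ExperimentFailure",
    "PruneStep",
    "PruneTrace",
    "count_links",
    "retention_test",
    "bulk_prune",
    "sequential_prune",
    "random_mass_elimination_survival",
    "mass_elimination_sweep",
    "single_attractor_experiment",
]


class ExperimentFailure(RuntimeError):
    """A stochastic protocol step exhausted its resample budget."""


@dataclass
class PruneStep:
    """One attempted link deletion (accepted or reinstated)."""

    links_remaining: int
    links_per_node: float
    accepted: bool
    mean_iterations: float  # NaN on rejected steps


@dataclass
class PruneTrace:
    """Ordered record of a sequential pruning run."""

    n_nodes: int
    steps: list[PruneStep] = field(default_factory=list)
    snapshots: list[tuple[int, np.ndarray]] = field(default_factory=list)
    final_network: np.ndarray | None = None

    @property
    def accepted_steps(self) -> list[PruneStep]:
        return [s for s in self.steps if s.accepted]


def count_links(w: np.ndarray) -> int:
    """Number of nonzero directed entries (diagonal included)."""
    return int(np.count_nonzero(w))


def retention_test(
    w: np.ndarray,
    s: np.ndarray,
    n_starts: int = 100,
    max_iters: int = 500,
    max_period: int = 4,
    rng: np.random.Generator | None = None,
) -> tuple[bool, float]:
    """Monte-Carlo check that the pair {s, −s} globally attracts fresh probes.

    Retained iff both s and its complement −s remain fixed points of ``w``
    *and* all ``n_starts`` fresh random probes converge to one of them.
    Requiring the full complement pair is the ±1 equivalent of demanding
    that no node's input ties at zero on the pattern: a node that loses all
    its incoming links (or balances them) would silently pin to +1, which
    leaves s itself fixed when s_i = +1 but destroys the pattern as a
    stored attractor pair.

    Returns ``(retained, mean_iterations)``; the mean is over converged
    probes and is NaN when the test aborts before any probe finishes.
    Probes ending in a foreign fixed point, a limit cycle of period ≤
    ``max_period``, or still unresolved after ``max_iters`` steps all count
    as retention failure.
    """
    if rng is None:
        rng = np.random.default_rng()
    starts = netgen.random_initial_states(w.shape[0], n_starts, rng)
    report = probe_basins(
        w, starts, [s], max_iters=max_iters, max_period=max_period,
        require_pairs=True,
    )
    return report.retained, report.mean_iterations


def bulk_prune(
    w: np.ndarray,
    s: np.ndarray,
    rng: np.random.Generator,
    target_links_per_node: float = 10.0,
    n_starts: int = 100,
    max_iters: int = 500,
    max_period: int = 4,
    resample_budget: int = 20,
) -> np.ndarray:
    """Remove most links at once, keeping ``round(target·N)`` chosen uniformly.

    The pruned net must pass the retention test; on failure a fresh random
    keep-set is drawn, up to ``resample_budget`` attempts.  A target at or
    above the current link count returns the matrix unchanged.
    """
    n = w.shape[0]
    keep_count = int(round(target_links_per_node * n))
    nz = np.flatnonzero(w)
    if keep_count >= nz.size:
        return w.copy()
    for _ in range(resample_budget):
        keep = rng.choice(nz.size, size=keep_count, replace=False)
        pruned = np.zeros_like(w)
        pruned.flat[nz[keep]] = w.flat[nz[keep]]
        retained, _ = retention_test(
            pruned, s, n_starts=n_starts, max_iters=max_iters,
            max_period=max_period, rng=rng,
        )
        if retained:
            return pruned
    raise ExperimentFailure(
        f"bulk prune to {keep_count} links failed the retention test "
        f"{resample_budget} times in a row (N={n})"
    )


def sequential_prune(
    w: np.ndarray,
    s: np.ndarray,
    rng: np.random.Generator,
    n_starts: int = 100,
    max_iters: int = 500,
    max_period: int = 4,
    snapshot_every: int = 25,
    probe_rng: np.random.Generator | None = None,
) -> PruneTrace:
    """Delete links one at a time until no single deletion survives testing.

    At each step a uniformly random eligible link is zeroed and a fresh
    retention test run.  Accepted deletions persist and reset every link's
    eligibility (losing one link may change which others are removable);
    rejected deletions are reinstated and the link becomes ineligible until
    the next acceptance.  The loop terminates — yielding the minimal
    skeleton T* in ``final_network`` — when a full pass over the remaining
    links produces only rejections.  Snapshots of the matrix are kept every
    ``snapshot_every`` accepted deletions.
    """
    if probe_rng is None:
        probe_rng = rng
    n = w.shape[0]
    current = w.copy()
    trace = PruneTrace(n_nodes=n)
    accepted_count = 0

    while True:
        order = rng.permutation(np.flatnonzero(current))
        accepted_this_round = False
        for flat_idx in order:
            saved = current.flat[flat_idx]
            current.flat[flat_idx] = 0
            retained, mean_iters = retention_test(
                current, s, n_starts=n_starts, max_iters=max_iters,
                max_period=max_period, rng=probe_rng,
            )
            links = count_links(current)
            if retained:
                trace.steps.append(PruneStep(links, links / n, True, mean_iters))
                accepted_count += 1
                if snapshot_every and accepted_count % snapshot_every == 0:
                    trace.snapshots.append((links, current.copy()))
                accepted_this_round = True
                break
            current.flat[flat_idx] = saved
            trace.steps.append(
                PruneStep(count_links(current), count_links(current) / n, False, mean_iters)
            )
        if not accepted_this_round:
            break

    trace.final_network = current
    trace.snapshots.append((count_links(current), current.copy()))
    return trace


def random_mass_elimination_survival(
    w: np.ndarray,
    s: np.ndarray,
    fraction_removed: float,
    rng: np.random.Generator,
    n_trials: int = 20,
    n_starts: int = 100,
    max_iters: int = 500,
    max_period: int = 4,
) -> float:
    """Fraction of trials in which blind mass deletion leaves ±s attracting.

    Each trial zeroes a fresh uniformly random ``fraction_removed`` share of
    the N² entries of ``w`` (no accept/reject feedback) and runs one
    retention test.  This is the robustness contrast to sequential pruning:
    the minimal skeleton dies with one more deletion, whereas the full net
    usually shrugs off random removal of the vast majority of its links.
    """
    if not 0.0 <= fraction_removed < 1.0:
        raise ValueError(f"fraction_removed must be in [0, 1), got {fraction_removed}")
    n = w.shape[0]
    remove_count = int(round(fraction_removed * n * n))
    survived = 0
    for _ in range(n_trials):
        removed = rng.choice(n * n, size=remove_count, replace=False)
        trial = w.copy()
        trial.flat[removed] = 0
        retained, _ = retention_test(
            trial, s, n_starts=n_starts, max_iters=max_iters,
            max_period=max_period, rng=rng,
        )
        survived += int(retained)
    return survived / n_trials


def mass_elimination_sweep(
    w: np.ndarray,
    s: np.ndarray,
    rng: np.random.Generator,
    percentages: list[float] | None = None,
    n_trials: int = 20,
    n_starts: int = 100,
    max_iters: int = 500,
    max_period: int = 4,
) -> tuple[float | None, dict[float, float]]:
    """Sweep removal percentages upward; report the largest with majority survival.

    Default grid: 80, 85, 90, 95 % in 5-point steps.  The sweep stops at the
    first percentage where at most half the trials retain the attractor.
    Returns ``(largest_majority_pct or None, {pct: survival_fraction})``.
    """
    if percentages is None:
        percentages = [80.0, 85.0, 90.0, 95.0]
    survivals: dict[float, float] = {}
    best: float | None = None
    for pct in percentages:
        frac = pct / 100.0
        surv = random_mass_elimination_survival(
            w, s, frac, rng, n_trials=n_trials, n_starts=n_starts,
            max_iters=max_iters, max_period=max_period,
        )
        survivals[pct] = surv
        if surv > 0.5:
            best = pct
        else:
            break
    return best, survivals


def single_attractor_experiment(
    n_nodes: int,
    seed: int | np.random.SeedSequence,
    n_starts: int = 100,
    bulk_target: float = 10.0,
    max_iters: int = 500,
    max_period: int = 4,
    snapshot_every: int = 25,
    resample_budget: int = 20,
) -> dict:
    """Full experiment-1 pipeline: build T, bulk-prune, prune to T*.

    Returns a dict with the attractor ``s``, the minimal skeleton
    ``tstar``, the bulk-pruned starting matrix, the :class:`PruneTrace`,
    and the per-stage seed spawn keys.
    """
    from .dynamics import outer_attractor_matrix

    streams, keys = netgen.seed_streams(
        seed, ["attractor", "bulk", "links", "probes"]
    )
    s = netgen.random_attractor(n_nodes, streams["attractor"])
    t_full = outer_attractor_matrix(s)
    t_bulk = bulk_prune(
        t_full, s, streams["bulk"], target_links_per_node=bulk_target,
        n_starts=n_starts, max_iters=max_iters, max_period=max_period,
        resample_budget=resample_budget,
    )
    trace = sequential_prune(
        t_bulk, s, streams["links"], n_starts=n_starts, max_iters=max_iters,
        max_period=max_period, snapshot_every=snapshot_every,
        probe_rng=streams["probes"],
    )
    return {
        "n_nodes": n_nodes,
        "s": s,
        "t_bulk": t_bulk,
        "tstar": trace.final_network,
        "trace": trace,
        "final_links": count_links(trace.final_network),
        "seed_keys": keys,
        "config": {
            "n_nodes": n_nodes,
            "n_starts": n_starts,
            "bulk_target": bulk_target,
            "max_iters": max_iters,
            "max_period": max_period,
            "snapshot_every": snapshot_every,
        },
    }
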
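"""Grafting and pruning a second orthogonal attractor on a minimal skeleton.

Starting from the minimal single-attractor skeleton T* (patterns stored as
±1 entries inherited from T = s sᵀ), a second pattern r with r·s = 0 is
embedded by the two-pattern Hebbian rule everywhere *except* on the links
T* already owns:

    U[i, j] = T*[i, j]              if (i, j) is a protected skeleton link,
    U[i, j] = s_i s_j + r_i r_j     otherwise.

Both s and r (and their complements) are fixed points of U: the skeleton
rows perturb the two-pattern input sums by at most the skeleton's row
degree, which is far below N.  The added links are then pruned — first in
bulk to ~15 links per node, then one at a time — while the protected
skeleton entries are never touched.  Accepted deletions must keep both
designated pairs {s, −s} and {r, −r} fixed and send every random probe to
one of the four designated terminals; the recorded fraction of probes
captured by ±r traces how the second basin collapses as connectivity
falls.

Once no further deletion can satisfy the two-attractor criterion, pruning
continues under the single-attractor criterion (probes must still end on a
designated fixed point, but the second pair is no longer required to stay
fixed), so the trace crosses the connectivity at which the second
attractor stops being supported as a fixed point at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import netgen
from .dynamics import is_fixed_point, probe_basins
from .pruning import ExperimentFailure, count_links

__all__ = [
    "DualStep",
    "DualTrace",
    "DualCheck",
    "build_dual_matrix",
    "dual_retention_test",
    "dual_bulk_prune",
    "dual_sequential_prune",
    "dual_attractor_experiment",
]


class ConstructionError(RuntimeError):
    """The dual matrix failed its designated-fixed-point verification."""


@dataclass
class DualStep:
    links_remaining: int
    links_per_node: float
    accepted: bool
    mean_iterations: float
    fraction_to_second: float  # NaN on rejected steps
    second_is_fixed_point: bool
    phase: int  # 1 = two-attractor criterion, 2 = single-attractor criterion


@dataclass
class DualTrace:
    n_nodes: int
    protected_mask: np.ndarray | None = None
    steps: list[DualStep] = field(default_factory=list)
    final_network: np.ndarray | None = None
    transition_step: int | None = None  # index of first phase-2 step
    second_loss_links_per_node: float | None = None

    @property
    def accepted_steps(self) -> list[DualStep]:
        return [s for s in self.steps if s.accepted]


@dataclass
class DualCheck:
    retained: bool
    fraction_to_second: float
    mean_iterations: float
    second_is_fixed_point: bool


def build_dual_matrix(
    tstar: np.ndarray, s: np.ndarray, r: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Two-pattern matrix U over the protected skeleton T*.

    Protected entries (the nonzero entries of ``tstar``) keep their
    skeleton values; every other entry takes the standard two-pattern
    Hebbian value s_i s_j + r_i r_j (in {−2, 0, 2}).  Verifies that s and
    r are both fixed points of the result before returning.

    Returns ``(u, protected_mask)``.
    """
    s = netgen.validate_state(s)
    r = netgen.validate_state(r, n_nodes=s.shape[0])
    if int(r.astype(np.int64) @ s.astype(np.int64)) != 0:
        raise ValueError("r must be exactly orthogonal to s")
    tstar = np.asarray(tstar)
    if tstar.shape != (s.shape[0], s.shape[0]):
        raise ValueError(f"tstar shape {tstar.shape} does not match N={s.shape[0]}")
    protected = tstar != 0
    u = (np.outer(s, s) + np.outer(r, r)).astype(np.int8)
    u[protected] = tstar[protected]
    bad = [
        name
        for name, v in (("s", s), ("-s", -s), ("r", r), ("-r", -r))
        if not is_fixed_point(u, v)
    ]
    if bad:
        raise ConstructionError(
            f"designated pattern(s) {', '.join(bad)} are not fixed points of U"
        )
    return u, protected


def dual_retention_test(
    u: np.ndarray,
    s: np.ndarray,
    r: np.ndarray,
    n_starts: int = 200,
    max_iters: int = 500,
    max_period: int = 4,
    rng: np.random.Generator | None = None,
    require_second_fixed: bool = True,
) -> DualCheck:
    """Monte-Carlo check of the two-attractor criterion.

    Retained iff the pair {s, −s} is fixed, the pair {r, −r} is fixed when
    ``require_second_fixed`` (the same complement-pair notion of support as
    in single-attractor retention), and every probe reaches a fixed point
    in {s, −s, r, −r}.  ``fraction_to_second`` is the share of probes
    captured by ±r, among all probes when every probe converged, NaN
    otherwise.  ``second_is_fixed_point`` reports whether the second pair
    is currently supported, regardless of retention.
    """
    if rng is None:
        rng = np.random.default_rng()
    second_supported = is_fixed_point(u, r) and is_fixed_point(u, -r)
    starts = netgen.random_initial_states(u.shape[0], n_starts, rng)
    report = probe_basins(
        u, starts, [s, r], max_iters=max_iters, max_period=max_period,
        require_pairs=[True, require_second_fixed],
    )
    frac2 = report.target_hits[1] / n_starts if report.retained else float("nan")
    return DualCheck(
        report.retained, float(frac2), report.mean_iterations, second_supported
    )


def dual_bulk_prune(
    u: np.ndarray,
    s: np.ndarray,
    r: np.ndarray,
    protected_mask: np.ndarray,
    rng: np.random.Generator,
    target_links_per_node: float = 15.0,
    n_starts: int = 200,
    max_iters: int = 500,
    max_period: int = 4,
    resample_budget: int = 20,
) -> np.ndarray:
    """Bulk-remove added links so ``round(target·N)`` total links remain.

    Protected skeleton entries are always kept; the survivors among the
    added links are drawn uniformly.  The result must pass the
    two-attractor retention test, with resampling on failure.
    """
    n = u.shape[0]
    total_target = int(round(target_links_per_node * n))
    n_protected = int(np.count_nonzero(u[protected_mask]))
    if total_target < n_protected:
        raise ValueError(
            f"target of {total_target} total links is below the "
            f"{n_protected} protected skeleton links"
        )
    removable = np.flatnonzero((u != 0) & ~protected_mask)
    keep_added = total_target - n_protected
    if keep_added >= removable.size:
        return u.copy()
    for _ in range(resample_budget):
        keep = rng.choice(removable.size, size=keep_added, replace=False)
        pruned = u.copy()
        drop = np.ones(removable.size, dtype=bool)
        drop[keep] = False
        pruned.flat[removable[drop]] = 0
        check = dual_retention_test(
            pruned, s, r, n_starts=n_starts, max_iters=max_iters,
            max_period=max_period, rng=rng,
        )
        if check.retained:
            return pruned
    raise ExperimentFailure(
        f"dual bulk prune to {total_target} links failed the retention test "
        f"{resample_budget} times in a row (N={n})"
    )


def dual_sequential_prune(
    u: np.ndarray,
    s: np.ndarray,
    r: np.ndarray,
    protected_mask: np.ndarray,
    rng: np.random.Generator,
    n_starts: int = 200,
    max_iters: int = 500,
    max_period: int = 4,
    probe_rng: np.random.Generator | None = None,
    stop_when_second_lost: bool = False,
) -> DualTrace:
    """One-at-a-time deletion of added links with accept/reject testing.

    Phase 1 accepts a deletion only if the full two-attractor criterion
    holds.  When an entire round of remaining added links is rejected, the
    run switches to phase 2 (single-attractor criterion: probes must reach
    a designated fixed point, but r need not remain fixed) and continues to
    full minimality; the trace marks the transition and records the
    links-per-node at the first accepted step where r is no longer a fixed
    point.  With ``stop_when_second_lost`` the run returns at that moment.

    Protected skeleton entries are never candidates and are asserted
    bit-identical at exit.
    """
    if probe_rng is None:
        probe_rng = rng
    n = u.shape[0]
    current = u.copy()
    skeleton = u.copy()
    skeleton[~protected_mask] = 0
    trace = DualTrace(n_nodes=n, protected_mask=protected_mask.copy())
    phase = 1

    while True:
        candidates = np.flatnonzero((current != 0) & ~protected_mask)
        if candidates.size == 0:
            break
        order = rng.permutation(candidates)
        accepted_this_round = False
        for flat_idx in order:
            saved = current.flat[flat_idx]
            current.flat[flat_idx] = 0
            check = dual_retention_test(
                current, s, r, n_starts=n_starts, max_iters=max_iters,
                max_period=max_period, rng=probe_rng,
                require_second_fixed=(phase == 1),
            )
            links = count_links(current)
            if check.retained:
                trace.steps.append(DualStep(
                    links, links / n, True, check.mean_iterations,
                    check.fraction_to_second, check.second_is_fixed_point, phase,
                ))
                if (
                    trace.second_loss_links_per_node is None
                    and not check.second_is_fixed_point
                ):
                    trace.second_loss_links_per_node = links / n
                    if stop_when_second_lost:
                        trace.final_network = current
                        _assert_protected(current, skeleton, protected_mask)
                        return trace
                accepted_this_round = True
                break
            current.flat[flat_idx] = saved
            links = count_links(current)
            trace.steps.append(DualStep(
                links, links / n, False, check.mean_iterations,
                check.fraction_to_second, check.second_is_fixed_point, phase,
            ))
        if not accepted_this_round:
            if phase == 1:
                phase = 2
                trace.transition_step = len(trace.steps)
            else:
                break

    trace.final_network = current
    _assert_protected(current, skeleton, protected_mask)
    return trace


def _assert_protected(current: np.ndarray, skeleton: np.ndarray, mask: np.ndarray) -> None:
    if not np.array_equal(current[mask], skeleton[mask]):
        raise AssertionError("protected skeleton entries were modified during pruning")


def dual_attractor_experiment(
    tstar: np.ndarray,
    s: np.ndarray,
    seed: int | np.random.SeedSequence,
    n_starts: int = 200,
    bulk_target: float = 15.0,
    n_verify_starts: int = 1000,
    max_iters: int = 500,
    max_period: int = 4,
    resample_budget: int = 20,
    stop_when_second_lost: bool = False,
) -> dict:
    """Full experiment-2 pipeline on a previously pruned skeleton.

    Draws r orthogonal to s, builds U, verifies with ``n_verify_starts``
    probes that the full construction sends every start to a designated
    attractor, bulk-prunes the added links, and runs the sequential dual
    prune.  Returns the trace plus all intermediate objects and seed keys.
    """
    n = tstar.shape[0]
    streams, keys = netgen.seed_streams(
        seed, ["partner", "verify", "bulk", "links", "probes"]
    )
    r = netgen.orthogonal_partner(s, streams["partner"])
    u_full, protected = build_dual_matrix(tstar, s, r)
    if n_verify_starts:
        check = dual_retention_test(
            u_full, s, r, n_starts=n_verify_starts, max_iters=max_iters,
            max_period=max_period, rng=streams["verify"],
        )
        if not check.retained:
            raise ConstructionError(
                "full dual matrix failed global-convergence verification"
            )
    u_bulk = dual_bulk_prune(
        u_full, s, r, protected, streams["bulk"],
        target_links_per_node=bulk_target, n_starts=n_starts,
        max_iters=max_iters, max_period=max_period,
        resample_budget=resample_budget,
    )
    trace = dual_sequential_prune(
        u_bulk, s, r, protected, streams["links"], n_starts=n_starts,
        max_iters=max_iters, max_period=max_period,
        probe_rng=streams["probes"], stop_when_second_lost=stop_when_second_lost,
    )
    return {
        "n_nodes": n,
        "s": s,
        "r": r,
        "u_full": u_full,
        "u_bulk": u_bulk,
        "protected_mask": protected,
        "trace": trace,
        "final_links": count_links(trace.final_network),
        "second_loss_links_per_node": trace.second_loss_links_per_node,
        "seed_keys": keys,
        "config": {
            "n_nodes": n,
            "n_starts": n_starts,
            "bulk_target": bulk_target,
            "n_verify_starts": n_verify_starts,
            "max_iters": max_iters,
            "max_period": max_period,
            "protected_links": int(np.count_nonzero(tstar)),
        },
    }
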
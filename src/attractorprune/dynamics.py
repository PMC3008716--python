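"""Synchronous threshold dynamics for Hopfield-type ±1 networks.

The network state is a vector x ∈ {−1, +1}^N.  A weight matrix W, with row
i holding the strengths of the links *received* by node i (entry W[i, j] is
the directed link from node j into node i), drives the synchronous update

    x_i[n+1] = +1  if  Σ_j W[i, j] · x_j[n] ≥ 0,   else  −1.

All nodes threshold their summed input at zero simultaneously; a node whose
input sums to exactly zero (including a node with no surviving incoming
links) takes the value +1.

A single pattern s is stored Hebb-style with the rank-1 outer product
W = s sᵀ, which makes both s and its complement −s fixed points of the
update.  Pruning entries of W breaks its symmetry, which admits limit
cycles under the synchronous update; trajectories are therefore classified
as fixed points, short limit cycles (period ≤ 4 by default), or
nonconvergent within the iteration cap.

The module also provides an exhaustive small-N oracle
(:func:`enumerate_attractors`) that evolves every one of the 2^N states to
its exact terminal cycle, and a vectorised batch engine
(:func:`probe_basins`) used by the pruning experiments to test hundreds of
random probe states per accepted link removal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netgen import validate_state

__all__ = [
    "FIXED_POINT",
    "LIMIT_CYCLE",
    "NONCONVERGENT",
    "ConvergenceResult",
    "Attractor",
    "ProbeReport",
    "outer_attractor_matrix",
    "step",
    "evolve",
    "is_fixed_point",
    "enumerate_attractors",
    "all_states_converge_to",
    "probe_basins",
]

FIXED_POINT = "fixed_point"
LIMIT_CYCLE = "limit_cycle"
NONCONVERGENT = "nonconvergent"

#: Hard ceiling on N for exhaustive enumeration (2^N states).
ENUMERATION_LIMIT = 20


@dataclass
class ConvergenceResult:
    """Outcome of evolving one initial state.

    ``iterations`` counts the update steps needed to first *reach* the
    recurring state (a start that is already a fixed point reports 0).
    ``terminal_states`` holds the fixed point, or the cycle states in the
    order visited; it is empty for a nonconvergent run.
    """

    outcome: str
    period: int | None
    iterations: int
    terminal_states: list[np.ndarray]

    @property
    def converged(self) -> bool:
        return self.outcome != NONCONVERGENT


@dataclass
class Attractor:
    """A terminal fixed point or cycle with its exact basin size."""

    states: list[np.ndarray]
    period: int
    basin_size: int


@dataclass
class ProbeReport:
    """Batched probe outcome from :func:`probe_basins`.

    ``target_hits[k]`` counts probes whose terminal fixed point equals the
    k-th target pattern *or its complement* (complement identification).
    ``iterations`` is per-probe, NaN where a probe did not finish (either
    genuinely nonconvergent or skipped after an early abort).
    """

    retained: bool
    target_hits: np.ndarray
    iterations: np.ndarray
    failure: str | None

    @property
    def mean_iterations(self) -> float:
        finished = self.iterations[~np.isnan(self.iterations)]
        return float(finished.mean()) if finished.size else float("nan")


def outer_attractor_matrix(s: np.ndarray) -> np.ndarray:
    """Rank-1 Hebbian weight matrix W[i, j] = s_i · s_j (diagonal included).

    The result is symmetric with the single nonzero eigenvalue N on the
    eigenvector s, so both s and −s are fixed points of the synchronous
    threshold update.
    """
    s = validate_state(s)
    return np.outer(s, s).astype(np.int8)


def step(w: np.ndarray, x: np.ndarray) -> np.ndarray:
    """One synchronous update of every node; ties (zero input sums) go to +1."""
    w = np.asarray(w)
    x = np.asarray(x)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"weight matrix must be square, got shape {w.shape}")
    if x.shape != (w.shape[0],):
        raise ValueError(
            f"state length {x.shape} does not match matrix of {w.shape[0]} nodes"
        )
    sums = w.astype(np.int64) @ x.astype(np.int64)
    return np.where(sums >= 0, 1, -1).astype(np.int8)


def is_fixed_point(w: np.ndarray, x: np.ndarray) -> bool:
    """True iff one synchronous update maps ``x`` to itself."""
    return bool(np.array_equal(step(w, x), np.asarray(x, dtype=np.int8)))


def evolve(
    w: np.ndarray,
    x0: np.ndarray,
    max_iters: int = 500,
    max_period: int = 4,
) -> ConvergenceResult:
    """Iterate the synchronous update until recurrence or the iteration cap.

    After each step the new state is compared with the last ``max_period``
    states; the first exact repeat at lag p classifies the trajectory as a
    fixed point (p = 1) or a limit cycle of period p.  If no repeat occurs
    within ``max_iters`` steps the trajectory is reported nonconvergent.
    """
    if max_iters < 1 or max_period < 1:
        raise ValueError("max_iters and max_period must both be >= 1")
    x = validate_state(x0, n_nodes=w.shape[0])
    history: list[np.ndarray] = [x]
    for t in range(1, max_iters + 1):
        y = step(w, history[-1])
        for p in range(1, min(len(history), max_period) + 1):
            if np.array_equal(y, history[-p]):
                if p == 1:
                    return ConvergenceResult(FIXED_POINT, 1, t - 1, [y])
                cycle = [h.copy() for h in history[-p:]]
                return ConvergenceResult(LIMIT_CYCLE, p, t - p, cycle)
        history.append(y)
        if len(history) > max_period + 1:
            history.pop(0)
    return ConvergenceResult(NONCONVERGENT, None, max_iters, [])


# ---------------------------------------------------------------------------
# Exhaustive small-N oracle
# ---------------------------------------------------------------------------

def _decode_states(n: int) -> np.ndarray:
    """All 2^n states as a (2^n, n) ±1 int8 array; bit i of the index maps
    to component i (+1 where the bit is set)."""
    ks = np.arange(1 << n, dtype=np.uint32)
    bits = (ks[:, None] >> np.arange(n)) & 1
    return np.where(bits == 1, 1, -1).astype(np.int8)


def enumerate_attractors(w: np.ndarray, max_nodes: int = ENUMERATION_LIMIT) -> list[Attractor]:
    """Exact attractor catalogue by evolving every one of the 2^N states.

    The full state-transition map is computed in one vectorised pass, then
    the functional graph is walked to label every state with its terminal
    cycle.  Returns one :class:`Attractor` per terminal (any period, not
    capped at 4), sorted by decreasing basin size; basin sizes sum to 2^N.

    Refuses N > ``max_nodes`` (default 20) since the cost is 2^N.
    """
    w = np.asarray(w)
    n = w.shape[0]
    if n > max_nodes:
        raise ValueError(
            f"exhaustive enumeration over 2^{n} states refused (limit {max_nodes} nodes)"
        )
    states = _decode_states(n)
    sums = states.astype(np.float64) @ w.T.astype(np.float64)
    nxt = np.where(sums >= 0.0, 1, 0).astype(np.uint64)
    weights = (np.uint64(1) << np.arange(n, dtype=np.uint64))
    succ = (nxt @ weights).astype(np.int64)

    comp = np.full(1 << n, -1, dtype=np.int64)
    cycles: list[list[int]] = []
    for start in range(1 << n):
        if comp[start] != -1:
            continue
        path: list[int] = []
        pos: dict[int, int] = {}
        x = start
        while comp[x] == -1 and x not in pos:
            pos[x] = len(path)
            path.append(x)
            x = int(succ[x])
        if comp[x] != -1:
            cid = int(comp[x])
        else:
            cid = len(cycles)
            cycles.append(path[pos[x]:])
        for y in path:
            comp[y] = cid

    basins = np.bincount(comp, minlength=len(cycles))
    attractors = [
        Attractor(
            states=[states[k].copy() for k in cyc],
            period=len(cyc),
            basin_size=int(basins[cid]),
        )
        for cid, cyc in enumerate(cycles)
    ]
    attractors.sort(key=lambda a: a.basin_size, reverse=True)
    return attractors


def all_states_converge_to(
    w: np.ndarray, targets: list[np.ndarray], max_nodes: int = ENUMERATION_LIMIT
) -> bool:
    """Exact global-convergence check: every state flows to a fixed point
    equal to one of ``targets`` (pass [s, −s] for complement-identified
    retention).  Exhaustive, so small N only."""
    targets = [np.asarray(t, dtype=np.int8) for t in targets]
    for att in enumerate_attractors(w, max_nodes=max_nodes):
        if att.period != 1:
            return False
        if not any(np.array_equal(att.states[0], t) for t in targets):
            return False
    return True


# ---------------------------------------------------------------------------
# Vectorised batch probe engine
# ---------------------------------------------------------------------------

def probe_basins(
    w: np.ndarray,
    starts: np.ndarray,
    targets: list[np.ndarray],
    max_iters: int = 500,
    max_period: int = 4,
    fail_fast: bool = True,
    require_pairs: bool | list[bool] = False,
) -> ProbeReport:
    """Evolve a batch of probe states and classify their terminals.

    A probe *succeeds* when it reaches a fixed point equal to ±t for one of
    the ``targets`` t (a complement is only acceptable if it is itself a
    fixed point of ``w``).  Any other outcome — a foreign fixed point, a
    limit cycle of period ≤ ``max_period``, or no recurrence within
    ``max_iters`` steps — is a failure.  ``retained`` is True iff every
    probe succeeds.

    ``require_pairs`` (a single flag or one flag per target) additionally
    demands that *both* t and −t be fixed points for the marked targets —
    the complement-pair notion of a pattern being "supported": because the
    input sums are linear, the complement −t can only fail while t survives
    through a node whose input sums to exactly zero on t, i.e. a tie.
    Pair-marked targets with a broken complement make the whole report a
    failure (``broken_target_pair``) before any probe is run.

    With ``fail_fast`` (the default, used inside pruning loops) the engine
    aborts at the first observed failure; probes still in flight then keep
    NaN iteration counts.  Probes are evolved simultaneously as the columns
    of one matrix, and finished columns are dropped from the working set,
    so the per-step cost shrinks as probes converge.
    """
    w = np.asarray(w)
    n = w.shape[0]
    starts = np.asarray(starts, dtype=np.int8)
    if starts.ndim != 2 or starts.shape[1] != n:
        raise ValueError(f"starts must have shape (count, {n}), got {starts.shape}")
    m = starts.shape[0]
    if isinstance(require_pairs, bool):
        require_pairs = [require_pairs] * len(targets)
    if len(require_pairs) != len(targets):
        raise ValueError("require_pairs must match the number of targets")

    # Acceptable terminal columns: each target and its complement, kept only
    # if actually a fixed point of w.
    hits = np.zeros(len(targets), dtype=np.int64)
    iterations = np.full(m, np.nan)
    accept_cols: list[np.ndarray] = []
    accept_label: list[int] = []
    for k, t in enumerate(targets):
        t = validate_state(t, n_nodes=n)
        fixed = [is_fixed_point(w, signed) for signed in (t, -t)]
        if require_pairs[k] and not all(fixed):
            return ProbeReport(False, hits, iterations, "broken_target_pair")
        for signed, ok in zip((t, -t), fixed):
            if ok:
                accept_cols.append(signed.astype(np.float64))
                accept_label.append(k)

    if not accept_cols:
        return ProbeReport(False, hits, iterations, "no_fixed_target")

    A = np.stack(accept_cols, axis=1)  # (n, K)
    labels = np.asarray(accept_label)
    wf = w.astype(np.float64)

    X = starts.T.astype(np.float64)  # (n, m) columns are live probes
    idx = np.arange(m)  # original probe index of each live column
    history: list[np.ndarray] = [X]
    failure: str | None = None

    for t_step in range(1, max_iters + 1):
        Y = np.where(wf @ X >= 0.0, 1.0, -1.0)
        period = np.zeros(Y.shape[1], dtype=np.int64)
        for p in range(1, min(len(history), max_period) + 1):
            match = (Y == history[-p]).all(axis=0) & (period == 0)
            period[match] = p
        fixed = period == 1
        cyclic = period > 1

        if fixed.any():
            scores = Y[:, fixed].T @ A  # exact match iff dot == n
            matched = scores == float(n)
            ok = matched.any(axis=1)
            fixed_idx = np.flatnonzero(fixed)
            good = fixed_idx[ok]
            iterations[idx[good]] = t_step - 1
            if good.size:
                which = matched[ok].argmax(axis=1)
                np.add.at(hits, labels[which], 1)
            if (~ok).any():
                failure = failure or "wrong_fixed_point"
        if cyclic.any():
            failure = failure or "limit_cycle"

        if failure is not None and fail_fast:
            return ProbeReport(False, hits, iterations, failure)

        done = fixed | cyclic
        if done.all():
            X = Y[:, :0]
            idx = idx[:0]
            break
        keep = ~done
        history.append(Y)
        if len(history) > max_period:
            history.pop(0)
        X = Y[:, keep]
        idx = idx[keep]
        history = [h[:, keep] for h in history]

    if idx.size:
        failure = failure or "nonconvergent"

    return ProbeReport(failure is None, hits, iterations, failure)
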
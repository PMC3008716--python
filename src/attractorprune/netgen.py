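"""Seeded generators for every random object the experiments consume.

All randomness in the pipeline flows through :class:`numpy.random.Generator`
instances.  Experiment drivers derive one child generator per purpose
(attractor pattern, bulk pruning, link selection, probe states, ...) from a
single master seed via :func:`seed_streams`, so each stage of an experiment
is independently reproducible.

States and patterns are vectors in {−1, +1}^N, stored as ``int8`` arrays:
−1 marks a quiescent node, +1 an active one.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "random_attractor",
    "orthogonal_partner",
    "random_initial_states",
    "seed_streams",
    "validate_state",
]


def validate_state(x: np.ndarray, n_nodes: int | None = None) -> np.ndarray:
    """Return ``x`` as an int8 ±1 vector, raising ``ValueError`` otherwise."""
    arr = np.asarray(x)
    if arr.ndim != 1:
        raise ValueError(f"state must be one-dimensional, got shape {arr.shape}")
    if n_nodes is not None and arr.shape[0] != n_nodes:
        raise ValueError(f"state has length {arr.shape[0]}, expected {n_nodes}")
    if not np.all(np.abs(arr) == 1):
        raise ValueError("state components must all be -1 or +1")
    return arr.astype(np.int8, copy=False)


def random_attractor(n_nodes: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a uniform random ±1 pattern of length ``n_nodes``.

    Each component is independently −1 or +1 with probability 1/2.  This is
    the designated-attractor vector s from which the Hebbian weight matrix
    is built.
    """
    if n_nodes < 2:
        raise ValueError(f"n_nodes must be >= 2, got {n_nodes}")
    return (2 * rng.integers(0, 2, size=n_nodes) - 1).astype(np.int8)


def orthogonal_partner(s: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw a uniform random ±1 vector r exactly orthogonal to ``s``.

    A ±1 vector r satisfies r·s = 0 iff it agrees with s on exactly N/2
    positions, so r is built constructively: choose N/2 agreement positions
    uniformly at random and negate s elsewhere.  Choosing the agreement
    subset uniformly makes r uniform over all exactly-orthogonal partners.

    Raises
    ------
    ValueError
        If N is odd — exact orthogonality of two ±1 vectors is impossible
        then, and an approximately orthogonal vector is never returned.
    """
    s = validate_state(s)
    n = s.shape[0]
    if n % 2 != 0:
        raise ValueError(
            f"no ±1 vector can be exactly orthogonal to a vector of odd length {n}"
        )
    agree = rng.choice(n, size=n // 2, replace=False)
    r = -s
    r[agree] = s[agree]
    return r


def random_initial_states(
    n_nodes: int, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``count`` independent uniform ±1 probe states, shape (count, N)."""
    if n_nodes < 2:
        raise ValueError(f"n_nodes must be >= 2, got {n_nodes}")
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    return (2 * rng.integers(0, 2, size=(count, n_nodes)) - 1).astype(np.int8)


def seed_streams(
    seed: int | np.random.SeedSequence, names: Sequence[str]
) -> tuple[dict[str, np.random.Generator], dict[str, list[int]]]:
    """Split a master seed into one named child generator per purpose.

    Children are produced with :meth:`numpy.random.SeedSequence.spawn`, so
    the streams are statistically independent and the mapping from master
    seed to child streams is stable across runs and platforms.

    Returns
    -------
    (streams, keys)
        ``streams`` maps each name to a fresh ``Generator``; ``keys`` maps
        each name to its spawn key (recorded in run metadata so any stage
        can be re-seeded in isolation).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    streams = {name: np.random.default_rng(child) for name, child in zip(names, children)}
    keys = {name: [int(k) for k in child.spawn_key] for name, child in zip(names, children)}
    return streams, keys
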
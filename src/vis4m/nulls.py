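"""Chance-level null models for alternation under memoryless uniform exploration.

The null explorer starts in a uniformly chosen arm and at every step moves to
one of the three arms other than its current arm, uniformly and with no
memory.  Under this model the probability that four consecutive entries
visit four distinct arms is 2/9 (~22%), the chance level against which
observed alternation is compared.  A four-choice null that allowed
self-transitions would instead give 4!/4^4 ~ 9.4%, inconsistent with the
22% benchmark, so self-transitions are excluded here (as they are from the
twelve transition types).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .maze import percent_alternation

__all__ = [
    "window_success_probability",
    "expected_alternation_percent",
    "simulate_null_sequence",
    "simulate_null_alternations",
    "null_alternation_test",
    "NullTestResult",
]


def window_success_probability(n_arms: int = 4) -> float:
    """Exact probability that ``n_arms`` consecutive entries are all distinct.

    Computed by exhaustive enumeration of the (n_arms-1)^(n_arms-1) equally
    likely continuations from an arbitrary starting arm.  For the four-arm
    maze this is 6/27 = 2/9; the three-arm analogue (classic Y-maze) gives
    1/2.
    """
    if n_arms < 2:
        raise ValueError("need at least 2 arms")
    k = n_arms
    start = 0
    successes = 0
    total = 0
    # each step is uniform over the k-1 arms other than the current one
    for steps in itertools.product(range(k - 1), repeat=k - 1):
        seq = [start]
        for s in steps:
            others = [a for a in range(k) if a != seq[-1]]
            seq.append(others[s])
        total += 1
        if len(set(seq)) == k:
            successes += 1
    return successes / total


def expected_alternation_percent(n_entries: int, denominator: str = "entries-2") -> float:
    """Expected alternation percent for an N-entry null sequence.

    By linearity of expectation over the N-3 overlapping windows:
    100 * (N-3) * (2/9) / (N-2) under the printed N-2 denominator
    (asymptote 22.22%), or 100 * 2/9 under the windows denominator.
    """
    if n_entries < 4:
        raise ValueError(f"need at least 4 entries, got {n_entries}")
    p = window_success_probability(4)
    if denominator == "entries-2":
        return 100.0 * (n_entries - 3) * p / (n_entries - 2)
    if denominator == "windows":
        return 100.0 * p
    raise ValueError(f"unknown denominator rule {denominator!r}")


def simulate_null_sequence(
    n_entries: int, rng: np.random.Generator, arms=("B", "G", "R", "W")
) -> list[str]:
    """One null sequence: first arm uniform, then uniform over the 3 others."""
    idx = _simulate_null_indices(1, n_entries, rng, n_arms=len(arms))[0]
    return [arms[i] for i in idx]


def _simulate_null_indices(
    n_seq: int, n_entries: int, rng: np.random.Generator, n_arms: int = 4
) -> np.ndarray:
    """Vectorized batch of null sequences as an (n_seq, n_entries) int array."""
    if n_entries < 1:
        raise ValueError("n_entries must be >= 1")
    out = np.empty((n_seq, n_entries), dtype=np.int64)
    out[:, 0] = rng.integers(0, n_arms, size=n_seq)
    if n_entries > 1:
        # offset in 1..n_arms-1 skips the current arm modulo n_arms
        offsets = rng.integers(1, n_arms, size=(n_seq, n_entries - 1))
        for j in range(1, n_entries):
            out[:, j] = (out[:, j - 1] + offsets[:, j - 1]) % n_arms
    return out


def simulate_null_alternations(
    n_sims: int, n_entries: int, rng: np.random.Generator,
    denominator: str = "entries-2",
) -> np.ndarray:
    """Alternation percentages of ``n_sims`` null sequences (vectorized)."""
    if n_entries < 4:
        raise ValueError("need at least 4 entries")
    idx = _simulate_null_indices(n_sims, n_entries, rng)
    # all-distinct check over sliding windows of 4
    w = np.lib.stride_tricks.sliding_window_view(idx, 4, axis=1)
    distinct = (
        (w[..., 0] != w[..., 1])
        & (w[..., 0] != w[..., 2])
        & (w[..., 0] != w[..., 3])
        & (w[..., 1] != w[..., 2])
        & (w[..., 1] != w[..., 3])
        & (w[..., 2] != w[..., 3])
    )
    successes = distinct.sum(axis=1)
    denom = (n_entries - 2) if denominator == "entries-2" else (n_entries - 3)
    return 100.0 * successes / denom


@dataclass(frozen=True)
class NullTestResult:
    observed_percent: float
    n_entries: int
    n_sims: int
    null_mean: float
    null_sd: float
    expected_percent: float
    empirical_p: float


def null_alternation_test(
    observed_percent: float,
    n_entries: int,
    n_sims: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> NullTestResult:
    """Two-sided Monte-Carlo test of an observed alternation percent vs chance.

    Uses the add-one (permutation-style) estimator
    p = (1 + #{null at least as extreme}) / (n_sims + 1) on the side of the
    observed deviation, doubled and capped at 1, so p is never exactly 0.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    sims = simulate_null_alternations(n_sims, n_entries, rng)
    null_mean = float(sims.mean())
    null_sd = float(sims.std(ddof=1))
    if observed_percent >= null_mean:
        tail = int(np.sum(sims >= observed_percent))
    else:
        tail = int(np.sum(sims <= observed_percent))
    p = min(1.0, 2.0 * (1 + tail) / (n_sims + 1))
    return NullTestResult(
        observed_percent=observed_percent,
        n_entries=n_entries,
        n_sims=n_sims,
        null_mean=null_mean,
        null_sd=null_sd,
        expected_percent=expected_alternation_percent(n_entries),
        empirical_p=p,
    )
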
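"""Semi-Markov simulator of four-arm free exploration, and likelihood-based
parameter recovery.

The generative mouse carries three interpretable traits:

* **preference** — a positive attractiveness weight per arm (e.g. an
  elevated red/dark weight mimics the innate dark preference);
* **working memory** — each of the last ``memory_span`` visited arms is
  recalled with probability ``memory_strength``; a remembered arm's weight
  is multiplied by the ``avoidance`` factor epsilon (epsilon < 1 promotes
  alternation, the hallmark of intact spontaneous alternation);
* **pairwise discriminability** — when recalling a visit to arm *b*, its
  identity is confused with another arm *c* with probability 1 - d(b, c).
  A low d(B, W) therefore makes the animal avoid the wrong arm of the
  blue/white pair, collapsing B<->W transitions while leaving overall
  activity untouched — the signature of a color-discrimination deficit
  rather than a memory deficit.

At every step the candidate arms are the three arms other than the current
one (re-entries into the same arm are not generated; transitions are defined
between distinct arms).  Dwell times are exponential and the inter-entry
interval is exponential with mean 60/entry_rate seconds, truncated at the
session end, so entry_rate controls the number of entries per 5-minute
session.

With memory_strength = 0 the generator reduces exactly to the memoryless
uniform null model (given uniform preferences).  The per-step choice
distribution is also available in closed form by enumerating the recall and
confusion outcomes (at most 5^memory_span terms), which powers an exact
step-wise likelihood for parameter fitting.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize

from .maze import COLOR_ARMS, EntryEvent, Session, collapse_reentries

__all__ = [
    "ExplorationParams",
    "RecoveryReport",
    "wt_params",
    "ad_params",
    "simulate_session",
    "simulate_cohort",
    "choice_probabilities",
    "sequence_log_likelihood",
    "fit_exploration_params",
]


def _pair(a: str, b: str) -> frozenset[str]:
    return frozenset({a, b})


@dataclass(frozen=True)
class ExplorationParams:
    """Generative parameters of the synthetic explorer.

    discriminability maps unordered arm pairs to d in [0, 1]; pairs absent
    from the mapping default to 1 (never confused).
    """

    preference: Mapping[str, float] = field(
        default_factory=lambda: {a: 1.0 for a in COLOR_ARMS}
    )
    memory_strength: float = 0.0  # m: P(recall a recent visit)
    memory_span: int = 3  # k: number of recent entries carried
    avoidance: float = 1.0  # epsilon: weight multiplier for remembered arms
    discriminability: Mapping[frozenset[str], float] = field(default_factory=dict)
    entry_rate: float = 6.0  # entries per minute
    dwell_mean: float = 6.0  # seconds per arm visit
    duration_s: float = 300.0

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.preference.values()):
            raise ValueError("preference weights must be positive")
        for name, v in (
            ("memory_strength", self.memory_strength),
            ("avoidance", self.avoidance),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for p, d in self.discriminability.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"discriminability {sorted(p)} must be in [0, 1]")
        if self.memory_span < 1:
            raise ValueError("memory_span must be >= 1")
        if self.entry_rate <= 0 or self.dwell_mean <= 0 or self.duration_s <= 0:
            raise ValueError("entry_rate, dwell_mean and duration_s must be positive")

    @property
    def arms(self) -> tuple[str, ...]:
        return tuple(sorted(self.preference))

    def d(self, a: str, b: str) -> float:
        return self.discriminability.get(_pair(a, b), 1.0)


def wt_params() -> ExplorationParams:
    """Wild-type color-mode preset: intact memory and discrimination,
    moderate dark (red-arm) preference."""
    return ExplorationParams(
        preference={"B": 1.0, "G": 1.0, "R": 1.4, "W": 1.0},
        memory_strength=0.80,
        avoidance=0.25,
        discriminability={},
        entry_rate=6.0,
        dwell_mean=6.0,
    )


def ad_params() -> ExplorationParams:
    """AD-model color-mode preset: hyperactive, weakened memory, stronger
    dark preference, and degraded blue/white and green/white
    discriminability (the color-vision deficit phenotype)."""
    return ExplorationParams(
        preference={"B": 0.85, "G": 1.1, "R": 1.9, "W": 0.85},
        memory_strength=0.60,
        avoidance=0.40,
        discriminability={_pair("B", "W"): 0.3, _pair("G", "W"): 0.5},
        entry_rate=8.0,
        dwell_mean=5.0,
    )


def _recall_outcomes(
    arm: str, params: ExplorationParams, arms: Sequence[str]
) -> list[tuple[str | None, float]]:
    """Possible recalled identities of one remembered visit to ``arm``.

    Returns (identity, probability) pairs: None = not recalled (prob 1-m);
    otherwise recalled as ``arm`` or confused with another arm c with
    probability m * (1 - d(arm, c)) each (normalized if the confusion mass
    exceeds 1).
    """
    m = params.memory_strength
    out: list[tuple[str | None, float]] = []
    if m < 1.0:
        out.append((None, 1.0 - m))
    if m > 0.0:
        others = [c for c in arms if c != arm]
        q = {c: 1.0 - params.d(arm, c) for c in others}
        total_conf = sum(q.values())
        scale = 1.0 / total_conf if total_conf > 1.0 else 1.0
        p_correct = 1.0 - min(total_conf, 1.0)
        if p_correct > 0:
            out.append((arm, m * p_correct))
        for c, qc in q.items():
            if qc > 0:
                out.append((c, m * qc * scale))
    return out


def _choice_given_remembered(
    current: str, remembered: frozenset[str], params: ExplorationParams,
    arms: Sequence[str],
) -> dict[str, float]:
    weights = {}
    for b in arms:
        if b == current:
            continue
        w = params.preference[b] * (params.avoidance if b in remembered else 1.0)
        weights[b] = w
    total = sum(weights.values())
    if total <= 0.0:
        # epsilon = 0 with every candidate remembered: fall back to preference
        weights = {b: params.preference[b] for b in weights}
        total = sum(weights.values())
    return {b: w / total for b, w in weights.items()}


def choice_probabilities(
    current: str,
    memory: Sequence[str],
    params: ExplorationParams,
) -> dict[str, float]:
    """Exact next-arm distribution given the recent-entry memory.

    ``memory`` is the sequence of the last <= memory_span entries (the most
    recent being the current arm).  The distribution marginalizes over the
    independent recall and confusion outcomes of each remembered visit.
    """
    arms = params.arms
    memory = list(memory)[-params.memory_span :]
    per_visit = [_recall_outcomes(a, params, arms) for a in memory]
    probs = {b: 0.0 for b in arms if b != current}
    for combo in itertools.product(*per_visit) if per_visit else [()]:
        p_combo = 1.0
        remembered = set()
        for identity, p in combo:
            p_combo *= p
            if identity is not None:
                remembered.add(identity)
        if p_combo == 0.0:
            continue
        cp = _choice_given_remembered(current, frozenset(remembered), params, arms)
        for b, p in cp.items():
            probs[b] += p_combo * p
    return probs


def simulate_session(
    params: ExplorationParams,
    mouse_id: str = "sim",
    genotype: str = "WT",
    sex: str = "M",
    age_months: float = 8.5,
    condition: str = "E",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Session:
    """Generate one session; deterministic given the seed/rng."""
    if rng is None:
        rng = np.random.default_rng(seed)
    arms = params.arms
    events: list[EntryEvent] = []
    seq: list[str] = []
    t = float(rng.exponential(60.0 / params.entry_rate))
    while t < params.duration_s:
        if not seq:
            pref = np.array([params.preference[a] for a in arms])
            arm = str(rng.choice(arms, p=pref / pref.sum()))
        else:
            probs = choice_probabilities(seq[-1], seq, params)
            labels = list(probs)
            arm = str(rng.choice(labels, p=np.array([probs[b] for b in labels])))
        gap = float(rng.exponential(60.0 / params.entry_rate))
        dwell = min(float(rng.exponential(params.dwell_mean)), gap)
        t_exit = min(t + dwell, params.duration_s)
        events.append(EntryEvent(arm=arm, t_enter=round(t, 3), t_exit=round(t_exit, 3)))
        seq.append(arm)
        t += gap
    return Session(
        mouse_id=mouse_id,
        genotype=genotype,
        sex=sex,
        age_months=age_months,
        condition=condition,
        events=events,
        duration_s=params.duration_s,
        arm_mode="color" if set(arms) == set(COLOR_ARMS) else "generic",
    )


def simulate_cohort(
    group_specs: Sequence[tuple[ExplorationParams, dict]],
    n_per_group: int,
    seed: int,
) -> list[Session]:
    """Reproducible cohort: ``n_per_group`` sessions per (params, metadata) spec.

    Metadata dicts supply Session fields (genotype, sex, age_months,
    condition); mouse ids are generated as ``<genotype><index>``.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    sessions = []
    for g, (params, meta) in enumerate(group_specs):
        meta = dict(meta)
        prefix = meta.pop("mouse_id_prefix", meta.get("genotype", f"G{g}"))
        for i in range(n_per_group):
            sessions.append(
                simulate_session(
                    params,
                    mouse_id=f"{prefix}-{i + 1:03d}",
                    rng=np.random.default_rng(rng.integers(0, 2**31 - 1)),
                    **meta,
                )
            )
    return sessions


# -- likelihood and parameter recovery ---------------------------------------


def _state_counts(
    sessions: Iterable[Session], memory_span: int
) -> dict[tuple[str, tuple[str, ...], str], int]:
    """Count (current arm, memory tuple, chosen arm) occurrences across sessions.

    Grouping identical states keeps the likelihood cost proportional to the
    number of distinct states (a few hundred) rather than total steps.
    """
    counts: dict[tuple[str, tuple[str, ...], str], int] = {}
    for s in sessions:
        seq, _ = collapse_reentries(s.raw_sequence)
        for i in range(1, len(seq)):
            mem = tuple(seq[max(0, i - memory_span) : i])
            key = (seq[i - 1], mem, seq[i])
            counts[key] = counts.get(key, 0) + 1
    return counts


def sequence_log_likelihood(
    sessions: Sequence[Session] | Session, params: ExplorationParams
) -> float:
    """Exact log-likelihood of the observed arm choices (first entries excluded)."""
    if isinstance(sessions, Session):
        sessions = [sessions]
    counts = _state_counts(sessions, params.memory_span)
    ll = 0.0
    cache: dict[tuple[str, tuple[str, ...]], dict[str, float]] = {}
    for (current, mem, choice), n in counts.items():
        key = (current, mem)
        if key not in cache:
            cache[key] = choice_probabilities(current, mem, params)
        p = cache[key].get(choice, 0.0)
        if p <= 0.0:
            return float("-inf")
        ll += n * math.log(p)
    return ll


_PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "memory_strength": (0.0, 1.0),
    "avoidance": (0.0, 1.0),
}


def _apply_free(
    base: ExplorationParams, free_names: Sequence[str], values: Sequence[float]
) -> ExplorationParams:
    scalar: dict[str, float] = {}
    disc = dict(base.discriminability)
    for name, v in zip(free_names, values):
        if name.startswith("d:"):
            a, b = name[2:].split(",")
            disc[_pair(a, b)] = float(v)
        else:
            scalar[name] = float(v)
    return replace(base, discriminability=disc, **scalar)


@dataclass(frozen=True)
class RecoveryReport:
    """Fit result: per-parameter estimate and profile-likelihood CI."""

    estimates: Mapping[str, float]
    ci: Mapping[str, tuple[float, float]]
    log_likelihood: float
    n_steps: int
    warnings: tuple[str, ...] = ()


def fit_exploration_params(
    sessions: Sequence[Session],
    base_params: ExplorationParams,
    free_params: Sequence[str],
    ci_level: float = 0.95,
) -> RecoveryReport:
    """Maximize the exact step-wise likelihood over the named free parameters.

    ``free_params`` entries are scalar names (``memory_strength``,
    ``avoidance``) or pairwise discriminabilities written ``d:A,B``.  All
    other parameters are held at ``base_params``.  Confidence intervals are
    profile-likelihood intervals from the chi-squared(1) likelihood-ratio
    cutoff, located by bisection on the profile.
    """
    if not sessions:
        raise ValueError("need at least one session")
    if not free_params:
        raise ValueError("no free parameters")
    counts = _state_counts(sessions, base_params.memory_span)
    n_steps = sum(counts.values())

    def nll(values: np.ndarray) -> float:
        p = _apply_free(base_params, free_params, values)
        ll = 0.0
        cache: dict = {}
        for (current, mem, choice), n in counts.items():
            key = (current, mem)
            if key not in cache:
                cache[key] = choice_probabilities(current, mem, p)
            prob = cache[key].get(choice, 0.0)
            if prob <= 0.0:
                return 1e12
            ll += n * math.log(prob)
        return -ll

    bounds = [
        _PARAM_BOUNDS.get(name, (0.0, 1.0)) for name in free_params
    ]
    x0 = []
    for name in free_params:
        if name.startswith("d:"):
            a, b = name[2:].split(",")
            x0.append(base_params.d(a, b))
        else:
            x0.append(getattr(base_params, name))
    x0 = np.clip(np.asarray(x0, dtype=float), 0.05, 0.95)

    res = optimize.minimize(
        nll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 200, "ftol": 1e-10},
    )
    best = res.x
    best_ll = -float(res.fun)

    notes: list[str] = []
    if not res.success:
        notes.append(f"optimizer did not report convergence: {res.message}")
    if n_steps < 50 * len(free_params):
        notes.append(
            f"only {n_steps} observed choices for {len(free_params)} free "
            "parameters; estimates may be weakly identified (wide CIs)"
        )

    from scipy.stats import chi2

    cutoff = chi2.ppf(ci_level, df=1) / 2.0

    def profile_nll(i: int, v: float) -> float:
        vals = best.copy()
        vals[i] = v
        return nll(vals)

    ci: dict[str, tuple[float, float]] = {}
    for i, name in enumerate(free_params):
        lo_bound, hi_bound = bounds[i]
        target = -best_ll + cutoff

        def above(v: float, i=i) -> float:
            return profile_nll(i, v) - target

        lo = lo_bound
        if above(lo_bound) > 0:
            lo = optimize.brentq(above, lo_bound, best[i], xtol=1e-4)
        hi = hi_bound
        if above(hi_bound) > 0:
            hi = optimize.brentq(above, best[i], hi_bound, xtol=1e-4)
        ci[name] = (float(lo), float(hi))

    if notes:
        for msg in notes:
            warnings.warn(msg, RuntimeWarning, stacklevel=2)
    return RecoveryReport(
        estimates={name: float(v) for name, v in zip(free_params, best)},
        ci=ci,
        log_likelihood=best_ll,
        n_steps=n_steps,
        warnings=tuple(notes),
    )
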
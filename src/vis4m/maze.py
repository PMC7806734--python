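"""Core data model for four-arm maze sessions and sequence-derived statistics.

The ViS4M (visual-stimuli four-arm maze) is an x-shaped enclosure whose four
arms carry controlled color (LED) or grayscale-object (contrast) stimuli.  A
session is five minutes of free exploration by one mouse; the raw record is
the ordered sequence of arm entries with entry/exit times.  Everything this
module computes — spontaneous alternation, per-arm entry and time fractions,
unidirectional/bidirectional transition profiles, and quartile selections for
chord diagrams — derives from that sequence.

Spontaneous alternation is scored over overlapping windows of four
consecutive entries: a window succeeds when its four arms are all distinct.
The percentage reported divides the success count by ``N - 2`` (N = number of
entries), the convention used for this maze; the ``N - 3`` variant (number of
windows, so a perfect explorer scores 100%) is available via
``denominator="windows"``.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "COLOR_ARMS",
    "CONTRAST_ARMS",
    "GENERIC_ARMS",
    "COLOR_LAYOUT",
    "MazeLayout",
    "EntryEvent",
    "Session",
    "AlternationResult",
    "TransitionProfile",
    "ordered_pairs",
    "unordered_pairs",
    "collapse_reentries",
    "percent_alternation",
    "percent_entries",
    "percent_time",
    "transition_profile",
    "select_quartile_transitions",
]

#: Arm vocabularies.  Color mode: Blue, Green, Red, White LEDs.  Contrast
#: mode: Black, Clear, Grey, White objects.  Generic: unlabeled arms.
COLOR_ARMS: tuple[str, ...] = ("B", "G", "R", "W")
CONTRAST_ARMS: tuple[str, ...] = ("B", "C", "G", "W")
GENERIC_ARMS: tuple[str, ...] = ("A1", "A2", "A3", "A4")

ARM_MODES: dict[str, tuple[str, ...]] = {
    "color": COLOR_ARMS,
    "contrast": CONTRAST_ARMS,
    "generic": GENERIC_ARMS,
}

CONDITIONS: tuple[str, ...] = ("NC", "L", "M", "H", "RH", "E", "CONTRAST")


@dataclass(frozen=True)
class MazeLayout:
    """Physical layout: four arm labels and the two facing (opposite) pairs.

    In the color-mode apparatus the blue and green arms face each other, as
    do the white and red arms; straight runs through the center therefore
    produce B<->G and R<->W transitions.
    """

    labels: tuple[str, str, str, str]
    facing_pairs: tuple[frozenset[str], frozenset[str]]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != 4:
            raise ValueError("a maze has exactly 4 distinct arm labels")
        covered = self.facing_pairs[0] | self.facing_pairs[1]
        if (
            len(self.facing_pairs[0]) != 2
            or len(self.facing_pairs[1]) != 2
            or covered != set(self.labels)
        ):
            raise ValueError("facing_pairs must partition the 4 labels into 2 pairs")

    def facing_partner(self, arm: str) -> str:
        for pair in self.facing_pairs:
            if arm in pair:
                (other,) = pair - {arm}
                return other
        raise KeyError(arm)


COLOR_LAYOUT = MazeLayout(
    labels=COLOR_ARMS,
    facing_pairs=(frozenset({"B", "G"}), frozenset({"R", "W"})),
)


@dataclass(frozen=True)
class EntryEvent:
    """One arm visit: label plus entry/exit times in seconds on the session clock."""

    arm: str
    t_enter: float
    t_exit: float

    def __post_init__(self) -> None:
        if self.t_enter < 0:
            raise ValueError(f"t_enter must be >= 0, got {self.t_enter}")
        if self.t_exit < self.t_enter:
            raise ValueError(
                f"t_exit ({self.t_exit}) must be >= t_enter ({self.t_enter})"
            )

    @property
    def dwell(self) -> float:
        return self.t_exit - self.t_enter


@dataclass
class Session:
    """One mouse x one condition x one 5-minute trial."""

    mouse_id: str
    genotype: str  # "WT" or "AD+"
    sex: str  # "M" or "F"
    age_months: float
    condition: str
    events: list[EntryEvent] = field(default_factory=list)
    duration_s: float = 300.0
    arm_mode: str = "color"
    distance_m: float | None = None
    speed_mps: float | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if self.age_months <= 0:
            raise ValueError("age_months must be positive")
        vocab = ARM_MODES[self.arm_mode]
        prev_exit = 0.0
        for ev in self.events:
            if ev.arm not in vocab:
                raise ValueError(
                    f"arm {ev.arm!r} not in {self.arm_mode!r} vocabulary {vocab}"
                )
            if ev.t_enter < prev_exit - 1e-9:
                raise ValueError(
                    f"events overlap: entry at {ev.t_enter} before previous exit {prev_exit}"
                )
            if ev.t_exit > self.duration_s + 1e-9:
                raise ValueError(
                    f"event exit {ev.t_exit} exceeds session duration {self.duration_s}"
                )
            prev_exit = ev.t_exit

    @property
    def arms(self) -> tuple[str, ...]:
        return ARM_MODES[self.arm_mode]

    @property
    def raw_sequence(self) -> list[str]:
        """Arm labels in entry order, including same-arm re-entries."""
        return [ev.arm for ev in self.events]

    @property
    def sequence(self) -> list[str]:
        """Arm labels with consecutive same-arm re-entries collapsed."""
        seq, _ = collapse_reentries(self.raw_sequence)
        return seq


@dataclass(frozen=True)
class AlternationResult:
    n_entries: int
    n_windows: int
    n_successes: int
    denominator: int
    percent: float


def ordered_pairs(arms: Sequence[str]) -> list[tuple[str, str]]:
    """The 12 ordered distinct-arm pairs in canonical (alphabetical) order."""
    labels = sorted(arms)
    return [(a, b) for a, b in itertools.product(labels, labels) if a != b]


def unordered_pairs(arms: Sequence[str]) -> list[frozenset[str]]:
    """The 6 unordered distinct-arm pairs."""
    labels = sorted(arms)
    return [frozenset(p) for p in itertools.combinations(labels, 2)]


def collapse_reentries(seq: Iterable[str]) -> tuple[list[str], int]:
    """Drop consecutive repeats (mouse exits to center and re-enters same arm).

    Returns the collapsed sequence and the number of repeats removed.
    Idempotent; an empty sequence maps to an empty sequence.
    """
    out: list[str] = []
    collapsed = 0
    for label in seq:
        if out and out[-1] == label:
            collapsed += 1
        else:
            out.append(label)
    return out, collapsed


def percent_alternation(
    seq: Sequence[str], denominator: str = "entries-2"
) -> AlternationResult:
    """Score spontaneous alternation over overlapping 4-entry windows.

    A window succeeds when its four entries are four distinct arms.
    ``denominator="entries-2"`` (default) divides by N-2, the maze's printed
    convention, which caps the score at 100*(N-3)/(N-2); ``"windows"``
    divides by the number of windows N-3 so a perfect sequence scores 100%.

    ``seq`` must be free of consecutive repeats (see ``collapse_reentries``)
    and contain at least 4 entries.
    """
    seq = list(seq)
    n = len(seq)
    if n < 4:
        raise ValueError(f"sequence too short for alternation (N={n} < 4)")
    for a, b in zip(seq, seq[1:]):
        if a == b:
            raise ValueError("sequence contains consecutive repeats; collapse first")
    n_windows = n - 3
    n_successes = sum(
        1 for i in range(n_windows) if len(set(seq[i : i + 4])) == 4
    )
    if denominator == "entries-2":
        denom = n - 2
    elif denominator == "windows":
        denom = n_windows
    else:
        raise ValueError(f"unknown denominator rule {denominator!r}")
    return AlternationResult(
        n_entries=n,
        n_windows=n_windows,
        n_successes=n_successes,
        denominator=denom,
        percent=100.0 * n_successes / denom,
    )


def percent_entries(
    seq: Sequence[str], arms: Sequence[str] | None = None
) -> dict[str, float]:
    """Percentage of entries per arm; sums to 100."""
    seq = list(seq)
    if not seq:
        raise ValueError("empty sequence")
    if arms is None:
        arms = sorted(set(seq))
    counts = Counter(seq)
    n = len(seq)
    return {a: 100.0 * counts.get(a, 0) / n for a in arms}


def percent_time(
    session: Session, arms: Sequence[str] | None = None
) -> dict[str, float]:
    """Percentage of in-arm time per arm.

    The denominator is total time inside the four arms; time in the center
    zone is excluded so the four percentages sum to 100.
    """
    if arms is None:
        arms = session.arms
    dwell: dict[str, float] = {a: 0.0 for a in arms}
    for ev in session.events:
        dwell[ev.arm] = dwell.get(ev.arm, 0.0) + ev.dwell
    total = sum(dwell.values())
    if total <= 0:
        raise ValueError("zero total dwell time")
    return {a: 100.0 * dwell[a] / total for a in arms}


@dataclass(frozen=True)
class TransitionProfile:
    """Counts and percentages over the 12 ordered and 6 unordered arm pairs."""

    arms: tuple[str, ...]
    uni_counts: Mapping[tuple[str, str], int]
    total_transitions: int

    @property
    def uni_percent(self) -> dict[tuple[str, str], float]:
        if self.total_transitions == 0:
            return {p: 0.0 for p in ordered_pairs(self.arms)}
        return {
            p: 100.0 * self.uni_counts[p] / self.total_transitions
            for p in ordered_pairs(self.arms)
        }

    @property
    def bi_percent(self) -> dict[frozenset[str], float]:
        uni = self.uni_percent
        return {
            frozenset({a, b}): uni[(a, b)] + uni[(b, a)]
            for a, b in itertools.combinations(sorted(self.arms), 2)
        }

    def count_matrix(self) -> list[list[int]]:
        """Square count matrix (rows = origin, cols = destination, zero diagonal)."""
        labels = sorted(self.arms)
        return [
            [0 if a == b else self.uni_counts[(a, b)] for b in labels]
            for a in labels
        ]


def transition_profile(
    seq: Sequence[str], arms: Sequence[str] | None = None
) -> TransitionProfile:
    """Tally consecutive ordered arm pairs; N entries give N-1 transitions."""
    seq = list(seq)
    if len(seq) < 2:
        raise ValueError("no transitions (need at least 2 entries)")
    if arms is None:
        arms = sorted(set(seq))
    arms = tuple(sorted(arms))
    counts = {p: 0 for p in ordered_pairs(arms)}
    for a, b in zip(seq, seq[1:]):
        if a == b:
            raise ValueError("self-transition found; collapse re-entries first")
        counts[(a, b)] += 1
    return TransitionProfile(
        arms=arms, uni_counts=counts, total_transitions=len(seq) - 1
    )


def select_quartile_transitions(
    profile: TransitionProfile, which: str
) -> list[tuple[str, str]]:
    """Top (Q4) or bottom (Q1) quartile of the 12 unidirectional transitions.

    Returns exactly 3 ordered pairs.  Ties are broken by the canonical
    alphabetical pair ordering (origin, then destination) so that the
    selection is deterministic.
    """
    pairs = ordered_pairs(profile.arms)
    uni = profile.uni_percent
    if which == "Q4_most_frequent":
        ranked = sorted(pairs, key=lambda p: (-uni[p], pairs.index(p)))
    elif which == "Q1_least_frequent":
        ranked = sorted(pairs, key=lambda p: (uni[p], pairs.index(p)))
    else:
        raise ValueError(
            f"which must be 'Q4_most_frequent' or 'Q1_least_frequent', got {which!r}"
        )
    return ranked[: len(pairs) // 4]
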
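"""Beat grids and perturbed click tracks for the Beat Alignment Test (BAT).

The perception half of the BAT plays a musical excerpt with metronome beeps
superimposed some seconds after onset.  Beeps are either aligned with the
annotated beat (on-beat), displaced by a fixed fraction of the inter-beat
interval (phase shift: constant misalignment), or played at a tempo a fixed
percentage off the musical tempo (period shift: misalignment that accumulates
over the beep train).  This module builds those stimuli from beat annotations
and assembles randomized trial batteries.

All times are in seconds, relative to excerpt onset.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AlignmentKind",
    "AlignmentCondition",
    "BeatGrid",
    "ClickTrack",
    "TrialSpec",
    "ON_BEAT",
    "make_beat_grid",
    "on_beat_click_track",
    "apply_phase_shift",
    "apply_period_shift",
    "build_battery",
    "default_condition_plan",
    "DEFAULT_BEEP_START",
]

#: Default offset (s) at which beeps begin within an excerpt.
DEFAULT_BEEP_START = 5.0


class AlignmentKind(str, enum.Enum):
    """How a click track relates to the musical beat."""

    ON_BEAT = "on_beat"
    PHASE = "phase"
    PERIOD = "period"


@dataclass(frozen=True)
class AlignmentCondition:
    """One stimulus condition of the beat perception task.

    Parameters
    ----------
    kind
        On-beat, phase-shifted, or period-shifted.
    magnitude
        Dimensionless shift size: fraction of the mean inter-beat interval
        for phase shifts (0.10 or 0.175 in the standard battery), fractional
        tempo change for period shifts (0.02).  Zero for on-beat.
    direction
        -1 for early beeps / faster tempo, +1 for late beeps / slower tempo.
        0 for on-beat.
    """

    kind: AlignmentKind
    magnitude: float = 0.0
    direction: int = 0

    def __post_init__(self) -> None:
        kind = AlignmentKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind is AlignmentKind.ON_BEAT:
            if self.magnitude:
                raise ValueError("on-beat condition must have zero magnitude")
        else:
            if not 0.0 < self.magnitude < 0.5:
                raise ValueError(
                    f"{kind.value} magnitude must lie in (0, 0.5), got {self.magnitude}"
                )
            if self.direction not in (-1, 1):
                raise ValueError("direction must be -1 (early/fast) or +1 (late/slow)")

    @property
    def is_on_beat(self) -> bool:
        return self.kind is AlignmentKind.ON_BEAT

    def label(self) -> str:
        if self.is_on_beat:
            return "on_beat"
        arrow = {-1: "early" if self.kind is AlignmentKind.PHASE else "fast",
                 1: "late" if self.kind is AlignmentKind.PHASE else "slow"}[self.direction]
        return f"{self.kind.value}_{self.magnitude:g}_{arrow}"


ON_BEAT = AlignmentCondition(AlignmentKind.ON_BEAT)


@dataclass(frozen=True)
class BeatGrid:
    """Annotated beat onsets of one musical excerpt.

    Invariants: onsets strictly increasing, at least two of them, all within
    ``[0, duration]``.  The mean inter-beat interval (IBI) derived from the
    onsets is the normalizer used throughout scoring.
    """

    excerpt_id: str
    beat_onsets: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        onsets = np.asarray(self.beat_onsets, dtype=float)
        object.__setattr__(self, "beat_onsets", onsets)
        if onsets.ndim != 1 or onsets.size < 2:
            raise ValueError("beat grid needs at least 2 beat onsets")
        if not np.all(np.diff(onsets) > 0):
            raise ValueError("beat onsets must be strictly increasing")
        if onsets[0] < 0 or onsets[-1] > self.duration:
            raise ValueError("beat onsets must lie within [0, duration]")

    @property
    def n_beats(self) -> int:
        return int(self.beat_onsets.size)

    @property
    def mean_ibi(self) -> float:
        """Mean inter-beat interval in seconds."""
        return float(np.mean(np.diff(self.beat_onsets)))


@dataclass(frozen=True)
class ClickTrack:
    """Beep onsets superimposed on an excerpt under one alignment condition."""

    excerpt_id: str
    condition: AlignmentCondition
    beep_onsets: np.ndarray
    beep_start: float

    def __post_init__(self) -> None:
        onsets = np.asarray(self.beep_onsets, dtype=float)
        object.__setattr__(self, "beep_onsets", onsets)
        if onsets.size and not np.all(np.diff(onsets) > 0):
            raise ValueError("beep onsets must be strictly increasing")
        if self.beep_start < 0:
            raise ValueError("beep_start must be >= 0")


@dataclass(frozen=True)
class TrialSpec:
    """One perception trial: an excerpt, its condition, and ground truth."""

    trial_index: int
    excerpt_id: str
    phase: str  # "practice" | "test"
    condition: AlignmentCondition
    truth: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.phase not in ("practice", "test"):
            raise ValueError("phase must be 'practice' or 'test'")
        object.__setattr__(self, "truth", self.condition.is_on_beat)


def make_beat_grid(
    tempo_bpm: float,
    n_beats: int,
    first_onset: float = 0.0,
    *,
    excerpt_id: str = "excerpt",
    duration: float | None = None,
) -> BeatGrid:
    """Build an isochronous beat grid at a given tempo.

    A stand-in for annotated musical beats: ``n_beats`` onsets spaced
    ``60 / tempo_bpm`` seconds apart starting at ``first_onset``.  When
    ``duration`` is omitted it extends one IBI past the final beat.
    """
    if tempo_bpm <= 0:
        raise ValueError("tempo_bpm must be positive")
    if n_beats < 2:
        raise ValueError("need at least 2 beats")
    if first_onset < 0:
        raise ValueError("first_onset must be >= 0")
    ibi = 60.0 / tempo_bpm
    onsets = first_onset + ibi * np.arange(n_beats)
    if duration is None:
        duration = float(onsets[-1] + ibi)
    return BeatGrid(excerpt_id=excerpt_id, beat_onsets=onsets, duration=duration)


def on_beat_click_track(grid: BeatGrid, beep_start: float = DEFAULT_BEEP_START) -> ClickTrack:
    """Click track exactly on the beat: the subset of beats at/after ``beep_start``."""
    beeps = grid.beat_onsets[grid.beat_onsets >= beep_start]
    return ClickTrack(grid.excerpt_id, ON_BEAT, beeps, beep_start)


def apply_phase_shift(
    grid: BeatGrid,
    magnitude: float,
    direction: int,
    beep_start: float = DEFAULT_BEEP_START,
) -> ClickTrack:
    """Displace every beep by ``direction * magnitude * mean IBI``.

    The misalignment is constant across the train: each beep sits the same
    fraction of an inter-beat interval before (direction -1) or after
    (direction +1) its beat.
    """
    cond = AlignmentCondition(AlignmentKind.PHASE, magnitude, direction)
    beats = grid.beat_onsets[grid.beat_onsets >= beep_start]
    beeps = beats + direction * magnitude * grid.mean_ibi
    return ClickTrack(grid.excerpt_id, cond, beeps, beep_start)


def apply_period_shift(
    grid: BeatGrid,
    magnitude: float,
    direction: int,
    beep_start: float = DEFAULT_BEEP_START,
) -> ClickTrack:
    """Play beeps at a tempo ``magnitude`` (fractionally) off the musical tempo.

    The first beep is anchored on the first beat at/after ``beep_start``;
    successive beeps are spaced ``mean IBI * (1 + direction * magnitude)``
    (direction +1 = slower, -1 = faster), so beep-to-beat misalignment grows
    linearly along the train.  Beeps never run past the excerpt duration.
    """
    cond = AlignmentCondition(AlignmentKind.PERIOD, magnitude, direction)
    beats = grid.beat_onsets[grid.beat_onsets >= beep_start]
    if beats.size == 0:
        return ClickTrack(grid.excerpt_id, cond, np.empty(0), beep_start)
    anchor = beats[0]
    spacing = grid.mean_ibi * (1.0 + direction * magnitude)
    n = int(np.floor((grid.duration - anchor) / spacing)) + 1
    beeps = anchor + spacing * np.arange(n)
    return ClickTrack(grid.excerpt_id, cond, beeps, beep_start)


def render_click_track(
    grid: BeatGrid,
    condition: AlignmentCondition,
    beep_start: float = DEFAULT_BEEP_START,
) -> ClickTrack:
    """Dispatch a condition to the matching click-track constructor."""
    if condition.is_on_beat:
        return on_beat_click_track(grid, beep_start)
    if condition.kind is AlignmentKind.PHASE:
        return apply_phase_shift(grid, condition.magnitude, condition.direction, beep_start)
    return apply_period_shift(grid, condition.magnitude, condition.direction, beep_start)


def default_condition_plan() -> list[AlignmentCondition]:
    """An example 17-trial condition plan for the standard battery.

    Eight on-beat trials and nine off-beat trials covering both phase
    magnitudes (10% and 17.5% of the IBI, early and late) and both period
    directions (2% fast and slow).  The per-condition counts of the original
    published battery are not public, so this plan is a documented, balanced
    default; any plan of :class:`AlignmentCondition` objects may be supplied
    to :func:`build_battery` instead.
    """
    phase, period = AlignmentKind.PHASE, AlignmentKind.PERIOD
    plan = [ON_BEAT] * 8
    plan += [
        AlignmentCondition(phase, 0.10, -1),
        AlignmentCondition(phase, 0.10, +1),
        AlignmentCondition(phase, 0.175, -1),
        AlignmentCondition(phase, 0.175, +1),
        AlignmentCondition(phase, 0.175, -1),
    ]
    plan += [
        AlignmentCondition(period, 0.02, -1),
        AlignmentCondition(period, 0.02, -1),
        AlignmentCondition(period, 0.02, +1),
        AlignmentCondition(period, 0.02, +1),
    ]
    return plan


DEFAULT_PRACTICE_PLAN = (
    ON_BEAT,
    AlignmentCondition(AlignmentKind.PHASE, 0.175, -1),
    AlignmentCondition(AlignmentKind.PERIOD, 0.02, +1),
)


def build_battery(
    excerpts: Sequence[BeatGrid],
    condition_plan: Sequence[AlignmentCondition] | None = None,
    n_practice: int = 3,
    seed: int | np.random.Generator | None = None,
    *,
    practice_plan: Sequence[AlignmentCondition] = DEFAULT_PRACTICE_PLAN,
) -> list[TrialSpec]:
    """Assemble a perception battery: practice trials, then shuffled test trials.

    Each test condition in ``condition_plan`` (default: the 17-trial example
    plan) is assigned to one excerpt and the test order is randomized with the
    given seed.  The first ``n_practice`` excerpts serve the practice trials,
    which keep a fixed order.
    """
    if condition_plan is None:
        condition_plan = default_condition_plan()
    n_test = len(condition_plan)
    if n_practice < 0:
        raise ValueError("n_practice must be >= 0")
    if n_practice > len(practice_plan):
        raise ValueError("not enough practice conditions for n_practice")
    if len(excerpts) < n_practice + n_test:
        raise ValueError(
            f"need {n_practice + n_test} excerpts (got {len(excerpts)}): "
            "each trial uses a distinct excerpt"
        )
    rng = np.random.default_rng(seed)
    trials: list[TrialSpec] = []
    for i in range(n_practice):
        trials.append(
            TrialSpec(i, excerpts[i].excerpt_id, "practice", practice_plan[i])
        )
    test_excerpts = excerpts[n_practice : n_practice + n_test]
    order = rng.permutation(n_test)
    for j, k in enumerate(order):
        trials.append(
            TrialSpec(
                n_practice + j,
                test_excerpts[k].excerpt_id,
                "test",
                condition_plan[k],
            )
        )
    return trials
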
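"""Scoring of Beat Alignment Test perception responses and tap records.

Perception ability is the percent of correct on/off-the-beat judgments over
the test trials.  Production ability is scored per tapping trial against the
excerpt's beat grid with three dimensionless measures:

* **asynchrony** — mean |tap - nearest beat| / mean IBI (phase-matching error),
* **CDEV** (coefficient of deviation) — mean |IRI_i - mean IBI| / mean IBI,
  where IRI are inter-response (tap-to-tap) intervals (tempo-matching error),
* **CoV** (coefficient of variation) — SD(IRI) / mean(IRI), tapping
  variability independent of the stimulus.

Trial scores are averaged within the two consecutive presentations of each
excerpt, then across excerpts, to give one score per participant and measure.
Invalid trials (too few taps, or no taps in the scoring window) propagate as
missing values, never as zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stimuli import BeatGrid

__all__ = [
    "TapTrial",
    "PerceptionResponse",
    "ParticipantScores",
    "TrialValidity",
    "percent_correct",
    "match_taps_to_beats",
    "asynchrony_score",
    "cdev_score",
    "cov_score",
    "validate_trial",
    "score_trial",
    "aggregate_participant",
    "score_taps_frame",
    "DEFAULT_MIN_TAPS",
]

DEFAULT_MIN_TAPS = 4


@dataclass(frozen=True)
class TapTrial:
    """One beat-production trial: the taps one participant made to one excerpt."""

    participant_id: str
    excerpt_id: str
    repetition: int
    tap_onsets: np.ndarray

    def __post_init__(self) -> None:
        onsets = np.asarray(self.tap_onsets, dtype=float)
        object.__setattr__(self, "tap_onsets", onsets)
        if self.repetition not in (1, 2):
            raise ValueError("repetition must be 1 or 2")
        if onsets.size > 1 and not np.all(np.diff(onsets) > 0):
            raise ValueError("tap onsets must be strictly increasing")

    @property
    def n_taps(self) -> int:
        return int(self.tap_onsets.size)


@dataclass(frozen=True)
class PerceptionResponse:
    """One on/off-the-beat judgment with its ground truth and confidence.

    ``judgment`` and ``truth`` are True for "on the beat".  Confidence is a
    1-7 Likert rating; it is carried as metadata and not analyzed.
    """

    participant_id: str
    trial_index: int
    judgment: bool
    truth: bool
    confidence: int = 4

    def __post_init__(self) -> None:
        if not (isinstance(self.confidence, (int, np.integer)) and 1 <= self.confidence <= 7):
            raise ValueError("confidence must be an integer in [1, 7]")

    @property
    def correct(self) -> bool:
        return self.judgment == self.truth


@dataclass(frozen=True)
class ParticipantScores:
    """Participant-level BAT summary: perception accuracy and production scores."""

    participant_id: str
    pct_correct: float
    asynchrony: float
    cdev: float
    cov: float
    n_valid_trials: int

    def __post_init__(self) -> None:
        if not math.isnan(self.pct_correct) and not 0.0 <= self.pct_correct <= 100.0:
            raise ValueError("pct_correct must lie in [0, 100]")
        for name in ("asynchrony", "cdev", "cov"):
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TrialValidity:
    valid: bool
    reason: str | None = None


def percent_correct(responses: Sequence[PerceptionResponse]) -> float:
    """Percent of judgments matching ground truth (practice trials excluded upstream)."""
    if len(responses) == 0:
        raise ValueError("cannot score an empty response list")
    return 100.0 * sum(r.correct for r in responses) / len(responses)


def match_taps_to_beats(
    taps: np.ndarray | Sequence[float], beats: np.ndarray | Sequence[float]
) -> np.ndarray:
    """Index of the nearest beat for each tap; ties go to the earlier beat.

    Beats may be matched by several taps.  Inputs must be sorted and nonempty.
    """
    taps = np.asarray(taps, dtype=float)
    beats = np.asarray(beats, dtype=float)
    if taps.size == 0 or beats.size == 0:
        raise ValueError("taps and beats must be nonempty")
    right = np.searchsorted(beats, taps)  # first beat >= tap
    left = np.clip(right - 1, 0, beats.size - 1)
    right = np.clip(right, 0, beats.size - 1)
    # strict inequality: at exactly half an IBI the earlier beat wins
    use_right = np.abs(beats[right] - taps) < np.abs(taps - beats[left])
    return np.where(use_right, right, left)


def asynchrony_score(trial: TapTrial, grid: BeatGrid) -> float:
    """Phase-matching error: mean |tap - nearest beat| normalized by mean IBI."""
    if trial.n_taps == 0:
        return float("nan")
    idx = match_taps_to_beats(trial.tap_onsets, grid.beat_onsets)
    dev = np.abs(trial.tap_onsets - grid.beat_onsets[idx])
    return float(np.mean(dev) / grid.mean_ibi)


def cdev_score(trial: TapTrial, grid: BeatGrid, variant: str = "per-interval") -> float:
    """Tempo-matching error (coefficient of deviation).

    ``per-interval`` (default): mean |IRI_i - mean IBI| / mean IBI, which
    penalizes unstable as well as mis-set tempo and equals |period scale - 1|
    for steady tapping.  ``aggregate``: |mean IRI - mean IBI| / mean IBI, the
    coarser reading in which fast and slow intervals can cancel.
    Needs at least 2 taps (1 inter-response interval); returns NaN otherwise.
    """
    if trial.n_taps < 2:
        return float("nan")
    iri = np.diff(trial.tap_onsets)
    ibi = grid.mean_ibi
    if variant == "per-interval":
        return float(np.mean(np.abs(iri - ibi)) / ibi)
    if variant == "aggregate":
        return float(abs(np.mean(iri) - ibi) / ibi)
    raise ValueError(f"unknown cdev variant {variant!r}")


def cov_score(trial: TapTrial) -> float:
    """Tapping variability: sample SD of inter-response intervals over their mean.

    Stimulus-independent (no beat grid involved) and invariant to uniform time
    rescaling.  Needs at least 3 taps (2 intervals); returns NaN otherwise.
    """
    if trial.n_taps < 3:
        return float("nan")
    iri = np.diff(trial.tap_onsets)
    return float(np.std(iri, ddof=1) / np.mean(iri))


def validate_trial(
    trial: TapTrial,
    grid: BeatGrid,
    min_taps: int = DEFAULT_MIN_TAPS,
    listen_window: float = 0.0,
) -> TrialValidity:
    """Screen a production trial before scoring.

    Invalid if it has fewer than ``min_taps`` taps (boundary inclusive:
    exactly ``min_taps`` is valid) or no tap after an initial beep-free
    listening window of ``listen_window`` seconds.
    """
    if trial.n_taps < min_taps:
        return TrialValidity(False, "too_few_taps")
    if listen_window > 0 and not np.any(trial.tap_onsets >= listen_window):
        return TrialValidity(False, "no_taps_after_listen_window")
    return TrialValidity(True)


def score_trial(
    trial: TapTrial,
    grid: BeatGrid,
    *,
    min_taps: int = DEFAULT_MIN_TAPS,
    cdev_variant: str = "per-interval",
) -> dict[str, float]:
    """All three production scores for one trial; NaN for invalid trials."""
    v = validate_trial(trial, grid, min_taps)
    if not v.valid:
        nan = float("nan")
        return {"asynchrony": nan, "cdev": nan, "cov": nan, "valid": 0.0}
    return {
        "asynchrony": asynchrony_score(trial, grid),
        "cdev": cdev_score(trial, grid, cdev_variant),
        "cov": cov_score(trial),
        "valid": 1.0,
    }


def _two_stage_mean(frame: pd.DataFrame, col: str) -> float:
    """Average repetitions within excerpt, then across excerpts, skipping NaN."""
    per_excerpt = frame.groupby("excerpt_id")[col].mean()
    per_excerpt = per_excerpt.dropna()
    return float(per_excerpt.mean()) if len(per_excerpt) else float("nan")


def aggregate_participant(
    participant_id: str,
    trials: Iterable[tuple[TapTrial, BeatGrid]],
    responses: Sequence[PerceptionResponse],
    *,
    min_taps: int = DEFAULT_MIN_TAPS,
    cdev_variant: str = "per-interval",
) -> ParticipantScores:
    """Participant-level scores from scored trials and perception responses.

    Production scores are averaged over the two consecutive repetitions of
    each excerpt (a lone valid repetition stands for its excerpt) and then
    across excerpts.  A participant with no valid production trial or no
    perception response is flagged by raising ``ValueError`` — mirroring the
    exclusion of participants who did not complete both tasks.
    """
    rows = []
    for trial, grid in trials:
        scores = score_trial(trial, grid, min_taps=min_taps, cdev_variant=cdev_variant)
        rows.append({"excerpt_id": trial.excerpt_id, **scores})
    frame = pd.DataFrame(rows)
    n_valid = int(frame["valid"].sum()) if len(frame) else 0
    if n_valid == 0 or len(responses) == 0:
        raise ValueError(
            f"participant {participant_id!r} excluded: incomplete battery "
            f"({n_valid} valid production trials, {len(responses)} responses)"
        )
    return ParticipantScores(
        participant_id=participant_id,
        pct_correct=percent_correct(responses),
        asynchrony=_two_stage_mean(frame, "asynchrony"),
        cdev=_two_stage_mean(frame, "cdev"),
        cov=_two_stage_mean(frame, "cov"),
        n_valid_trials=n_valid,
    )


def score_taps_frame(
    taps: pd.DataFrame,
    grids: Mapping[str, BeatGrid],
    *,
    min_taps: int = DEFAULT_MIN_TAPS,
    cdev_variant: str = "per-interval",
) -> pd.DataFrame:
    """Vectorized trial scoring of a long-format tap log.

    ``taps`` has one row per tap with columns ``participant_id, excerpt_id,
    repetition, tap_onset_s``.  Returns one row per trial with columns
    ``participant_id, excerpt_id, repetition, n_taps, asynchrony, cdev, cov``.
    Equivalent to :func:`score_trial` applied per trial (tested), but runs the
    nearest-beat match once per excerpt across all participants.
    """
    taps = taps.sort_values(
        ["participant_id", "excerpt_id", "repetition", "tap_onset_s"], kind="stable"
    ).reset_index(drop=True)
    parts = []
    for excerpt_id, sub in taps.groupby("excerpt_id", sort=False):
        grid = grids[excerpt_id]
        beats = grid.beat_onsets
        onsets = sub["tap_onset_s"].to_numpy()
        idx = match_taps_to_beats(onsets, beats)
        sub = sub.assign(_abs_dev=np.abs(onsets - beats[idx]) / grid.mean_ibi)
        g = sub.groupby(["participant_id", "repetition"], sort=False)
        out = g.agg(n_taps=("tap_onset_s", "size"), asynchrony=("_abs_dev", "mean"))
        iri = g["tap_onset_s"].diff()
        sub = sub.assign(_iri=iri, _iri_dev=np.abs(iri - grid.mean_ibi) / grid.mean_ibi)
        g2 = sub.groupby(["participant_id", "repetition"], sort=False)
        if cdev_variant == "per-interval":
            out["cdev"] = g2["_iri_dev"].mean()
        else:
            out["cdev"] = (g2["_iri"].mean() - grid.mean_ibi).abs() / grid.mean_ibi
        out["cov"] = g2["_iri"].std(ddof=1) / g2["_iri"].mean()
        out = out.reset_index()
        out.insert(1, "excerpt_id", excerpt_id)
        parts.append(out)
    scored = pd.concat(parts, ignore_index=True)
    invalid = scored["n_taps"] < min_taps
    scored.loc[invalid, ["asynchrony", "cdev", "cov"]] = np.nan
    # < 2 taps -> no IRI; < 3 -> no IRI spread: already NaN from groupby ops
    return scored


def participant_table(
    scored_trials: pd.DataFrame,
    responses: pd.DataFrame,
) -> pd.DataFrame:
    """Collapse trial scores and responses to one row per participant.

    ``scored_trials`` comes from :func:`score_taps_frame`; ``responses`` has
    columns ``participant_id, judgment, truth`` (booleans), test trials only.
    Participants lacking either task are dropped.
    """
    valid = scored_trials.dropna(subset=["asynchrony"])
    per_excerpt = (
        scored_trials.groupby(["participant_id", "excerpt_id"])[
            ["asynchrony", "cdev", "cov"]
        ].mean()
    )
    prod = per_excerpt.groupby("participant_id").mean()
    prod["n_valid_trials"] = valid.groupby("participant_id").size()
    resp = responses.assign(correct=responses["judgment"] == responses["truth"])
    pct = 100.0 * resp.groupby("participant_id")["correct"].mean()
    out = prod.join(pct.rename("pct_correct"), how="inner").reset_index()
    return out[
        ["participant_id", "pct_correct", "asynchrony", "cdev", "cov", "n_valid_trials"]
    ]
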
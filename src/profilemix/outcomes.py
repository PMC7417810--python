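"""Episode outcome calculus and cohort inclusion rules.

Thresholds follow the national routine-outcome-measurement conventions:
caseness is PHQ-9 >= 10 or GAD-7 >= 8; reliable change is a movement of at
least 6 PHQ-9 points or 4 GAD-7 points.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "PHQ_CASENESS",
    "GAD_CASENESS",
    "PHQ_RELIABLE",
    "GAD_RELIABLE",
    "ImprovementRule",
    "EndStatus",
    "ScorePair",
    "EpisodeScores",
    "OutcomeFlags",
    "is_case",
    "deterioration",
    "reliable_improvement",
    "recovery",
    "reliable_recovery",
    "attrition",
    "episode_flags",
    "apply_inclusion",
    "flags_to_frame",
]

PHQ_CASENESS = 10
GAD_CASENESS = 8
PHQ_RELIABLE = 6
GAD_RELIABLE = 4

PHQ_RANGE = (0, 27)
GAD_RANGE = (0, 21)


class ScoreError(ValueError):
    """Score outside the instrument range."""


class ImprovementRule(str, Enum):
    """How reliable improvement interacts with reliable deterioration.

    ``STRICT`` (default): a reliable drop on either scale counts only when
    there is no simultaneous reliable rise on the other — improvement and
    deterioration are then mutually exclusive.  ``EITHER`` is the literal
    either-scale reading without that guard.
    """

    STRICT = "strict"
    EITHER = "either"


class EndStatus(str, Enum):
    COMPLETED = "completed"
    DROPPED_OUT = "dropped_out"
    DECLINED = "declined"
    OTHER = "other"


@dataclass(frozen=True)
class ScorePair:
    """A (PHQ-9, GAD-7) score pair."""

    phq: int
    gad: int

    def __post_init__(self) -> None:
        if not PHQ_RANGE[0] <= self.phq <= PHQ_RANGE[1]:
            raise ScoreError(f"PHQ-9 score {self.phq} outside {PHQ_RANGE}")
        if not GAD_RANGE[0] <= self.gad <= GAD_RANGE[1]:
            raise ScoreError(f"GAD-7 score {self.gad} outside {GAD_RANGE}")


@dataclass(frozen=True)
class EpisodeScores:
    """Baseline and end-of-treatment scores for one episode of care."""

    baseline: ScorePair
    final: ScorePair | None
    n_sessions: int
    end_status: EndStatus = EndStatus.COMPLETED

    def __post_init__(self) -> None:
        if self.n_sessions < 0:
            raise ScoreError("n_sessions must be non-negative")
        if self.final is not None and self.n_sessions < 1:
            raise ScoreError("final scores require at least one session")


@dataclass(frozen=True)
class OutcomeFlags:
    caseness_baseline: bool
    recovered: bool
    reliably_improved: bool
    reliably_recovered: bool
    deteriorated: bool
    attrition: bool

    FIELDS = (
        "caseness_baseline",
        "recovered",
        "reliably_improved",
        "reliably_recovered",
        "deteriorated",
        "attrition",
    )


def is_case(s: ScorePair) -> bool:
    """Clinical caseness: PHQ-9 >= 10 or GAD-7 >= 8."""
    return s.phq >= PHQ_CASENESS or s.gad >= GAD_CASENESS


def deterioration(baseline: ScorePair, final: ScorePair) -> bool:
    """Reliable rise on either scale (>= 6 PHQ-9 or >= 4 GAD-7 points)."""
    return (
        final.phq - baseline.phq >= PHQ_RELIABLE
        or final.gad - baseline.gad >= GAD_RELIABLE
    )


def reliable_improvement(
    baseline: ScorePair,
    final: ScorePair,
    rule: ImprovementRule = ImprovementRule.STRICT,
) -> bool:
    """Reliable drop on either scale, optionally barring a reliable rise."""
    improved = (
        baseline.phq - final.phq >= PHQ_RELIABLE
        or baseline.gad - final.gad >= GAD_RELIABLE
    )
    if rule is ImprovementRule.STRICT:
        return improved and not deterioration(baseline, final)
    return improved


def recovery(baseline: ScorePair, final: ScorePair) -> bool:
    """Caseness at baseline, below caseness on both measures at the end."""
    return is_case(baseline) and final.phq < PHQ_CASENESS and final.gad < GAD_CASENESS


def reliable_recovery(
    baseline: ScorePair,
    final: ScorePair,
    rule: ImprovementRule = ImprovementRule.STRICT,
) -> bool:
    """Recovery together with reliable improvement."""
    return recovery(baseline, final) and reliable_improvement(baseline, final, rule)


def attrition(e: EpisodeScores) -> bool:
    """Dropped out or declined after more than two sessions."""
    return (
        e.end_status in (EndStatus.DROPPED_OUT, EndStatus.DECLINED)
        and e.n_sessions > 2
    )


def episode_flags(
    e: EpisodeScores, rule: ImprovementRule = ImprovementRule.STRICT
) -> OutcomeFlags:
    """All outcome flags for one episode; change flags need final scores."""
    has_final = e.final is not None
    return OutcomeFlags(
        caseness_baseline=is_case(e.baseline),
        recovered=has_final and recovery(e.baseline, e.final),
        reliably_improved=has_final and reliable_improvement(e.baseline, e.final, rule),
        reliably_recovered=has_final and reliable_recovery(e.baseline, e.final, rule),
        deteriorated=has_final and deterioration(e.baseline, e.final),
        attrition=attrition(e),
    )


# exclusion reasons, in precedence order
REASON_MISSINGNESS = "missingness"
REASON_SESSIONS = "sessions"
REASON_CASENESS = "caseness"


def apply_inclusion(records: Sequence) -> tuple[list, dict[str, int]]:
    """Filter a cohort to analysable episodes.

    A record is kept when (i) at most two of its nine indicators are missing,
    (ii) it has a baseline and at least one further score (>= 2 sessions with
    a final score present), and (iii) it meets baseline caseness.  The tally
    counts exclusions by the first failing rule, checked in the order
    missingness -> sessions -> caseness.

    Records are duck-typed: each needs ``indicators`` (with ``n_missing()``)
    and ``scores`` (an :class:`EpisodeScores`).
    """
    kept: list = []
    tally = {REASON_MISSINGNESS: 0, REASON_SESSIONS: 0, REASON_CASENESS: 0}
    for rec in records:
        if rec.indicators.n_missing() > 2:
            tally[REASON_MISSINGNESS] += 1
            continue
        scores: EpisodeScores = rec.scores
        if scores.final is None or scores.n_sessions < 2:
            tally[REASON_SESSIONS] += 1
            continue
        if not is_case(scores.baseline):
            tally[REASON_CASENESS] += 1
            continue
        kept.append(rec)
    return kept, tally


def flags_to_frame(flags: Iterable[OutcomeFlags]):
    """One row per episode, one boolean column per outcome flag."""
    import pandas as pd

    return pd.DataFrame(
        [{f: getattr(fl, f) for f in OutcomeFlags.FIELDS} for fl in flags]
    )
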
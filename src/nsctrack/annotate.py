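"""Event annotation on lineage forests.

Implements the observational rules used to score NSC behavior on the imaging
grid: divisions from quiescence (at least two division-free imaging
intervals, ~4-5 days, before cytokinesis), the MC/DC/DC+k time-point scheme,
division modes by daughter deltaA status, per-track deltaA trajectories,
delaminations, daughter-pair area asymmetry, and post-division outcomes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .model import (
    DELTA_POS_THRESHOLD,
    Event,
    LineageForest,
    Track,
    ValidationError,
    delta_status,
)

__all__ = [
    "DivisionEvent",
    "DivisionMode",
    "Mode",
    "Trajectory",
    "Outcome",
    "detect_divisions",
    "classify_division_mode",
    "classify_delta_trajectory",
    "pair_area_asymmetry",
    "detect_delaminations",
    "post_division_outcome",
]

MIN_QUIET_INTERVALS = 2
ASYMMETRY_THRESHOLD = 0.20
POST_DIVISION_MIN_DAYS = 4.0


class Mode(str, enum.Enum):
    NEG_NEG = "neg_neg"
    NEG_POS = "neg_pos"
    POS_POS = "pos_pos"
    UNCLASSIFIABLE = "unclassifiable"


class Trajectory(str, enum.Enum):
    ALWAYS_ON = "always_on"
    ALWAYS_OFF = "always_off"
    SWITCH_ON = "switch_on"
    SWITCH_OFF = "switch_off"
    MIXED = "mixed"


class Outcome(str, enum.Enum):
    REQUIESCENCE = "requiescence"
    REITERATIVE_DIVISION = "reiterative_division"
    DELAMINATION = "delamination"
    CENSORED = "censored"


@dataclass(frozen=True)
class DivisionEvent:
    mother_track: str
    daughter_tracks: tuple[str, str]
    division_tp: int          # mother's final time point (MC)
    from_quiescence: bool
    mother_area: Optional[float]
    mother_status: Optional[bool]


@dataclass(frozen=True)
class DivisionMode:
    horizon: int
    mode: Mode


def detect_divisions(
    forest: LineageForest,
    min_quiet_intervals: int = MIN_QUIET_INTERVALS,
    threshold: int = DELTA_POS_THRESHOLD,
) -> list[DivisionEvent]:
    """One :class:`DivisionEvent` per branching node of the forest.

    ``from_quiescence`` is true iff the mother shows at least
    ``min_quiet_intervals`` division-free imaging intervals immediately
    before cytokinesis (her whole observed history, since mid-track events
    are structurally excluded).  Mother area and deltaA status are read at
    the last pre-division time point (MC).
    """
    events = []
    children = forest.children_map()
    for mother_id in sorted(children):
        kids = children[mother_id]
        mother = forest[mother_id]
        mc = mother.points[-1]
        events.append(
            DivisionEvent(
                mother_track=mother_id,
                daughter_tracks=(kids[0], kids[1]),
                division_tp=mc.tp_index,
                from_quiescence=mother.n_intervals >= min_quiet_intervals,
                mother_area=mc.area,
                mother_status=delta_status(mc, threshold),
            )
        )
    return events


def classify_division_mode(
    event: DivisionEvent,
    forest: LineageForest,
    horizon: int,
    threshold: int = DELTA_POS_THRESHOLD,
    allow_last_observation: bool = False,
) -> DivisionMode:
    """Division mode from the daughters' deltaA statuses at DC+``horizon``.

    DC is each daughter's first time point.  Strict by default: a daughter
    with no observation exactly ``horizon`` points after DC makes the event
    unclassifiable.  With ``allow_last_observation`` the nearest earlier
    scored point is used instead.  Order of daughters is immaterial.
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    statuses = []
    for did in event.daughter_tracks:
        d = forest[did]
        target = d.first_tp + horizon
        point = d.point_at_tp(target)
        if point is None and allow_last_observation:
            point = d.points[-1] if d.last_tp < target else None
        status = delta_status(point, threshold) if point is not None else None
        if status is None:
            return DivisionMode(horizon=horizon, mode=Mode.UNCLASSIFIABLE)
        statuses.append(status)
    n_pos = sum(statuses)
    mode = {0: Mode.NEG_NEG, 1: Mode.NEG_POS, 2: Mode.POS_POS}[n_pos]
    return DivisionMode(horizon=horizon, mode=mode)


def classify_delta_trajectory(
    track: Track, threshold: int = DELTA_POS_THRESHOLD
) -> Trajectory:
    """Classify the ordered deltaA status sequence of one track."""
    statuses = track.statuses(threshold)
    if not statuses:
        raise ValidationError(f"track {track.track_id}: no scored points")
    changes = sum(a != b for a, b in zip(statuses, statuses[1:]))
    if changes == 0:
        return Trajectory.ALWAYS_ON if statuses[0] else Trajectory.ALWAYS_OFF
    if changes == 1:
        return Trajectory.SWITCH_ON if statuses[-1] else Trajectory.SWITCH_OFF
    return Trajectory.MIXED


def pair_area_asymmetry(
    a1: float, a2: float, threshold_frac: float = ASYMMETRY_THRESHOLD
) -> bool:
    """True iff the two areas differ by at least ``threshold_frac`` of the
    larger one (inclusive at the threshold)."""
    if a1 <= 0 or a2 <= 0:
        raise ValidationError("areas must be positive")
    return abs(a1 - a2) / max(a1, a2) >= threshold_frac


def detect_delaminations(
    forest: LineageForest, threshold: int = DELTA_POS_THRESHOLD
) -> pd.DataFrame:
    """Table of delamination events (track interruptions before movie end)
    with the area and deltaA status at the final point."""
    rows = []
    for track in sorted(forest, key=lambda t: t.track_id):
        last = track.points[-1]
        if last.event is Event.DELAMINATION:
            rows.append(
                {
                    "track_id": track.track_id,
                    "tp_index": last.tp_index,
                    "last_area": last.area,
                    "last_status": delta_status(last, threshold),
                }
            )
    return pd.DataFrame(rows, columns=["track_id", "tp_index", "last_area", "last_status"])


def post_division_outcome(
    event: DivisionEvent,
    forest: LineageForest,
    min_days: float = POST_DIVISION_MIN_DAYS,
    min_quiet_intervals: int = MIN_QUIET_INTERVALS,
) -> dict[str, Outcome]:
    """Per-daughter outcome after a division.

    A daughter whose fish could not be followed for at least ``min_days``
    after the division (the movie ends too soon) is censored, whatever she
    did: conditioning on potential rather than realized follow-up avoids
    selectively retaining fast dividers.  Otherwise, a daughter that divides
    again without meeting the quiet-interval criterion (fewer than
    ``min_quiet_intervals`` division-free imaging intervals) underwent a
    reiterative division; a daughter whose next division itself qualifies as
    a division from quiescence returned to quiescence first and is scored as
    requiescence, as is a daughter with no event over the observation
    window.  Delamination is its own category.
    """
    fish_end: dict[str, float] = {}
    for t in forest:
        fish_end[t.fish_id] = max(fish_end.get(t.fish_id, 0.0), t.last_day)
    out = {}
    for did in event.daughter_tracks:
        d = forest[did]
        if fish_end[d.fish_id] - d.first_day < min_days:
            out[did] = Outcome.CENSORED
            continue
        ev = d.terminal_event
        if ev is Event.DIVISION:
            if d.n_intervals < min_quiet_intervals:
                out[did] = Outcome.REITERATIVE_DIVISION
            else:
                out[did] = Outcome.REQUIESCENCE
        elif ev is Event.DELAMINATION:
            out[did] = Outcome.DELAMINATION
        elif d.last_day - d.first_day < min_days:
            out[did] = Outcome.CENSORED
        else:
            out[did] = Outcome.REQUIESCENCE
    return out


def divisions_frame(events: list[DivisionEvent]) -> pd.DataFrame:
    """Flatten division events into a table (one row per event)."""
    return pd.DataFrame(
        [
            {
                "mother_track": e.mother_track,
                "daughter1": e.daughter_tracks[0],
                "daughter2": e.daughter_tracks[1],
                "division_tp": e.division_tp,
                "from_quiescence": e.from_quiescence,
                "mother_area": e.mother_area,
                "mother_status": e.mother_status,
            }
            for e in events
        ],
        columns=[
            "mother_track", "daughter1", "daughter2", "division_tp",
            "from_quiescence", "mother_area", "mother_status",
        ],
    )
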
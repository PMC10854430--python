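"""Domain types and table I/O for neural-stem-cell lineage tracks.

The in-memory data model mirrors what an intravital-imaging tracking tool
exports: one row per cell per imaging time point, cells grouped into tracks,
tracks linked into lineage trees by parent -> daughter edges created at each
cytokinesis.  Apical areas are in um^2, deltaA reporter expression is scored
on a 0-3 intensity scale, and the proliferation marker (an MCM5/PCNA analog)
is a boolean flag.

Missing values are encoded as empty CSV fields and carried as ``None`` in
memory; an area of 0 is invalid, never a stand-in for "missing".
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "Event",
    "Treatment",
    "TrackPoint",
    "Track",
    "LineageForest",
    "CellSnapshot",
    "RateEstimate",
    "ParseError",
    "ValidationError",
    "read_tracks",
    "write_tracks",
    "read_snapshots",
    "write_snapshots",
    "delta_status",
]

TRACK_COLUMNS = [
    "fish_id",
    "treatment",
    "track_id",
    "parent_id",
    "tp_index",
    "day",
    "area_um2",
    "delta_score",
    "marker_on",
    "event",
]

SNAPSHOT_COLUMNS = ["hemisphere_id", "cell_id", "state", "area_um2", "delta_positive"]

#: default deltaA positivity threshold: any visible reporter signal (score >= 1)
DELTA_POS_THRESHOLD = 1

#: default admissible day gaps between consecutive imaging time points
DEFAULT_GAPS = (2, 3)


class ParseError(ValueError):
    """A track/snapshot table row could not be parsed."""


class ValidationError(ValueError):
    """A structural invariant of the data model is violated."""


class Event(str, enum.Enum):
    NONE = "none"
    DIVISION = "division"
    DELAMINATION = "delamination"


class Treatment(str, enum.Enum):
    CONTROL = "control"
    LY = "LY"


class SnapshotState(str, enum.Enum):
    QNSC = "qNSC"
    ANSC_SINGLET = "aNSC_singlet"
    ANP = "aNP"


@dataclass(frozen=True)
class TrackPoint:
    """One cell observation at one imaging time point."""

    tp_index: int
    day: float
    area: Optional[float] = None
    delta_score: Optional[int] = None
    marker_on: Optional[bool] = None
    event: Event = Event.NONE

    def __post_init__(self):
        if self.tp_index < 0:
            raise ValidationError(f"tp_index must be >= 0, got {self.tp_index}")
        if self.day < 0:
            raise ValidationError(f"day must be >= 0, got {self.day}")
        if self.area is not None and not self.area > 0:
            raise ValidationError(f"area must be > 0 um^2 or missing, got {self.area}")
        if self.delta_score is not None and self.delta_score not in (0, 1, 2, 3):
            raise ValidationError(
                f"delta_score must be in {{0,1,2,3}} or missing, got {self.delta_score}"
            )


def delta_status(point: TrackPoint, threshold: int = DELTA_POS_THRESHOLD) -> Optional[bool]:
    """deltaA positivity of a point: score >= ``threshold``.

    Any visible reporter signal counts as positive under the default
    threshold of 1.  A missing score propagates as ``None``; it is never
    silently treated as negative.
    """
    if point.delta_score is None:
        return None
    return point.delta_score >= threshold


@dataclass
class Track:
    """One cell's time series, from first detection to division/delamination/censoring."""

    track_id: str
    fish_id: str
    treatment: Treatment
    parent_id: Optional[str]
    points: list[TrackPoint] = field(default_factory=list)

    def validate(self, allowed_gaps: Optional[Sequence[float]] = DEFAULT_GAPS) -> None:
        if not self.points:
            raise ValidationError(f"track {self.track_id}: no points")
        for prev, cur in zip(self.points, self.points[1:]):
            if cur.tp_index != prev.tp_index + 1:
                raise ValidationError(
                    f"track {self.track_id}: tp_index not consecutive "
                    f"({prev.tp_index} -> {cur.tp_index})"
                )
            gap = cur.day - prev.day
            if gap <= 0:
                raise ValidationError(
                    f"track {self.track_id}: days not increasing at tp {cur.tp_index}"
                )
            if allowed_gaps is not None and not any(
                math.isclose(gap, g, abs_tol=1e-9) for g in allowed_gaps
            ):
                raise ValidationError(
                    f"track {self.track_id}: day gap {gap} not in allowed set "
                    f"{sorted(allowed_gaps)}"
                )
        n_events = sum(p.event is not Event.NONE for p in self.points)
        if n_events > 1:
            raise ValidationError(f"track {self.track_id}: more than one event")
        for p in self.points[:-1]:
            if p.event is not Event.NONE:
                raise ValidationError(
                    f"track {self.track_id}: event {p.event.value} at non-final "
                    f"tp {p.tp_index}"
                )

    @property
    def first_tp(self) -> int:
        return self.points[0].tp_index

    @property
    def last_tp(self) -> int:
        return self.points[-1].tp_index

    @property
    def first_day(self) -> float:
        return self.points[0].day

    @property
    def last_day(self) -> float:
        return self.points[-1].day

    @property
    def terminal_event(self) -> Event:
        return self.points[-1].event

    @property
    def n_intervals(self) -> int:
        """Number of imaging intervals spanned by the track."""
        return len(self.points) - 1

    def point_at_tp(self, tp_index: int) -> Optional[TrackPoint]:
        i = tp_index - self.first_tp
        if 0 <= i < len(self.points):
            return self.points[i]
        return None

    def areas(self) -> list[float]:
        return [p.area for p in self.points if p.area is not None]

    def statuses(self, threshold: int = DELTA_POS_THRESHOLD) -> list[bool]:
        """Ordered deltaA statuses over the scored points (missing skipped)."""
        out = []
        for p in self.points:
            s = delta_status(p, threshold)
            if s is not None:
                out.append(s)
        return out


@dataclass
class LineageForest:
    """Tracks linked by parent -> daughter edges into division trees."""

    tracks: dict[str, Track] = field(default_factory=dict)
    #: optional simulator ground truth (set by :mod:`nsctrack.simulate`)
    truth: Optional[object] = None

    def add(self, track: Track) -> None:
        if track.track_id in self.tracks:
            raise ValidationError(f"duplicate track_id {track.track_id}")
        self.tracks[track.track_id] = track

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks.values())

    def __getitem__(self, track_id: str) -> Track:
        return self.tracks[track_id]

    def children_of(self, track_id: str) -> list[Track]:
        return sorted(
            (t for t in self.tracks.values() if t.parent_id == track_id),
            key=lambda t: t.track_id,
        )

    def roots(self) -> list[Track]:
        return [t for t in self.tracks.values() if t.parent_id is None]

    def children_map(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for t in self.tracks.values():
            if t.parent_id is not None:
                out.setdefault(t.parent_id, []).append(t.track_id)
        for v in out.values():
            v.sort()
        return out

    def validate(self, allowed_gaps: Optional[Sequence[float]] = DEFAULT_GAPS) -> None:
        """Check all per-track and cross-track invariants; raise on the first failure."""
        for t in self.tracks.values():
            t.validate(allowed_gaps)
            if t.parent_id is not None and t.parent_id not in self.tracks:
                raise ValidationError(
                    f"track {t.track_id}: unknown parent {t.parent_id}"
                )
        children = self.children_map()
        for pid, kids in children.items():
            if len(kids) != 2:
                raise ValidationError(
                    f"track {pid}: has {len(kids)} children, every division "
                    "must produce exactly 2 daughters"
                )
            parent = self.tracks[pid]
            if parent.terminal_event is not Event.DIVISION:
                raise ValidationError(
                    f"track {pid}: has children but no terminal division event"
                )
            for kid in kids:
                k = self.tracks[kid]
                if k.first_tp != parent.last_tp + 1:
                    raise ValidationError(
                        f"track {kid}: first tp {k.first_tp} != parent's final "
                        f"tp {parent.last_tp} + 1"
                    )
                if k.fish_id != parent.fish_id or k.treatment != parent.treatment:
                    raise ValidationError(
                        f"track {kid}: fish/treatment differs from parent {pid}"
                    )
        # acyclicity: walking parent links must terminate at a root
        for t in self.tracks.values():
            seen = set()
            cur: Optional[str] = t.track_id
            while cur is not None:
                if cur in seen:
                    raise ValidationError(f"cycle through track {t.track_id}")
                seen.add(cur)
                cur = self.tracks[cur].parent_id
        for pid, kids in children.items():
            parent = self.tracks[pid]
            if parent.points[-1].event is not Event.DIVISION:
                raise ValidationError(f"track {pid}: children without division event")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in sorted(self.tracks.values(), key=lambda t: t.track_id):
            for p in t.points:
                rows.append(
                    {
                        "fish_id": t.fish_id,
                        "treatment": t.treatment.value,
                        "track_id": t.track_id,
                        "parent_id": t.parent_id if t.parent_id is not None else "",
                        "tp_index": p.tp_index,
                        "day": p.day,
                        "area_um2": p.area if p.area is not None else "",
                        "delta_score": p.delta_score if p.delta_score is not None else "",
                        "marker_on": _bool_to_field(p.marker_on),
                        "event": p.event.value,
                    }
                )
        return pd.DataFrame(rows, columns=TRACK_COLUMNS)


@dataclass(frozen=True)
class CellSnapshot:
    """A cell record from a fixed-tissue style static quantification."""

    cell_id: str
    hemisphere_id: str
    state: SnapshotState
    area: float
    delta_positive: bool

    def __post_init__(self):
        if not self.area > 0:
            raise ValidationError(f"cell {self.cell_id}: area must be > 0")


@dataclass(frozen=True)
class RateEstimate:
    """A per-day rate with a 95% CI and the derived doubling time ln(2)/rate."""

    rate: float
    ci_low: float
    ci_high: float
    n_events: int
    unit: str = "per day"

    def __post_init__(self):
        if self.rate < 0:
            raise ValidationError(f"rate must be >= 0, got {self.rate}")
        if not (self.ci_low <= self.rate <= self.ci_high):
            raise ValidationError(
                f"CI [{self.ci_low}, {self.ci_high}] does not bracket rate {self.rate}"
            )

    @property
    def doubling_time(self) -> float:
        """Days to double at this rate (also the exponential median lifetime)."""
        return math.log(2) / self.rate

    def to_dict(self) -> dict:
        d = {
            "rate": self.rate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_events": self.n_events,
            "unit": self.unit,
        }
        d["doubling_time_days"] = (
            math.log(2) / self.rate if self.rate > 0 else float("inf")
        )
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------


def _bool_to_field(v: Optional[bool]) -> str:
    if v is None:
        return ""
    return "1" if v else "0"


def _parse_bool(raw: str, line: int, col: str) -> Optional[bool]:
    if raw == "":
        return None
    if raw in ("1", "True", "true"):
        return True
    if raw in ("0", "False", "false"):
        return False
    raise ParseError(f"line {line}: bad boolean {raw!r} in column {col}")


def read_tracks(
    path,
    allowed_gaps: Optional[Sequence[float]] = DEFAULT_GAPS,
    validate: bool = True,
) -> LineageForest:
    """Read a long-format track table (CSV) into a validated :class:`LineageForest`.

    Rows are grouped by ``track_id`` and sorted by ``tp_index``; input row
    order is immaterial.  Malformed rows raise :class:`ParseError` naming the
    line; structural violations raise :class:`ValidationError` naming the
    track.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    forest = LineageForest()
    df = df.reset_index()  # keep original line numbers (header = line 1)
    for track_id, grp in df.groupby("track_id", sort=True):
        points = []
        first = grp.iloc[0]
        for _, row in grp.iterrows():
            line = int(row["index"]) + 2
            try:
                tp_index = int(row["tp_index"])
                day = float(row["day"])
                area = float(row["area_um2"]) if row["area_um2"] != "" else None
                score = int(row["delta_score"]) if row["delta_score"] != "" else None
            except ValueError as exc:
                raise ParseError(f"line {line}: {exc}") from exc
            marker = _parse_bool(row["marker_on"], line, "marker_on")
            try:
                event = Event(row["event"]) if row["event"] != "" else Event.NONE
            except ValueError as exc:
                raise ParseError(f"line {line}: unknown event {row['event']!r}") from exc
            try:
                points.append(
                    TrackPoint(
                        tp_index=tp_index,
                        day=day,
                        area=area,
                        delta_score=score,
                        marker_on=marker,
                        event=event,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"track {track_id}: {exc}") from exc
            if row["fish_id"] != first["fish_id"] or row["treatment"] != first["treatment"]:
                raise ValidationError(
                    f"track {track_id}: fish_id/treatment not constant within track"
                )
        points.sort(key=lambda p: p.tp_index)
        try:
            treatment = Treatment(first["treatment"])
        except ValueError as exc:
            raise ParseError(
                f"track {track_id}: unknown treatment {first['treatment']!r}"
            ) from exc
        forest.add(
            Track(
                track_id=str(track_id),
                fish_id=first["fish_id"],
                treatment=treatment,
                parent_id=first["parent_id"] if first["parent_id"] != "" else None,
                points=points,
            )
        )
    if validate:
        forest.validate(allowed_gaps)
    return forest


def write_tracks(forest: LineageForest, path) -> None:
    """Write a forest back to the long-format CSV schema of :func:`read_tracks`."""
    forest.to_frame().to_csv(path, index=False)


def read_snapshots(path) -> pd.DataFrame:
    """Read a static cell-snapshot table (CSV) and validate it."""
    df = pd.read_csv(path, dtype={"hemisphere_id": str, "cell_id": str})
    missing = [c for c in SNAPSHOT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    bad_state = set(df["state"]) - {s.value for s in SnapshotState}
    if bad_state:
        raise ParseError(f"{path}: unknown states {sorted(bad_state)}")
    if not (df["area_um2"] > 0).all():
        bad = df.loc[~(df["area_um2"] > 0), "cell_id"].tolist()
        raise ValidationError(f"nonpositive area for cells {bad[:5]}")
    df["delta_positive"] = df["delta_positive"].astype(bool)
    return df[SNAPSHOT_COLUMNS]


def write_snapshots(df: pd.DataFrame, path) -> None:
    df[SNAPSHOT_COLUMNS].to_csv(path, index=False)
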
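"""Stochastic generator of synthetic NSC lineage forests and snapshot tables.

The generator implements the lineage-progression model the analysis modules
assume, on the imaging grid the study design imposes (observations every 2-3
days for ~43 days):

* quiescent NSCs activate with a status-dependent per-day hazard
  (``gamma_neg`` for deltaA-negative, ``gamma_pos`` for deltaA-positive
  cells), optionally modulated by apical area through a logistic link;
* once activated the proliferation marker switches on and cytokinesis follows
  after an exponential delay (rate ``lambda_act``);
* each division splits the mother's apical area into two daughters that sum
  exactly to it, with a symmetric relative imbalance;
* deltaA-negative mothers divide asymmetrically: one daughter stays negative,
  the other switches the reporter on at the division time point or the next
  one; deltaA-positive mothers produce two positive daughters of unequal
  score, a small fraction of which later converts to a binary ON/OFF pair;
* quiescent areas grow multiplicatively (negative cells by ~30% over 40
  days, positive cells not at all); small deltaA-positive cells delaminate;
* rare deltaA switches occur in tracks that never divide.

All randomness flows through a single ``numpy`` generator seeded from one
integer, so a (params, n_tracks, seed) triple reproduces a forest exactly.
The generator also returns a ground-truth event log so downstream annotation
can be tested against an exact oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    Event,
    LineageForest,
    SnapshotState,
    Track,
    TrackPoint,
    Treatment,
    ValidationError,
)

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "imaging_grid",
    "simulate_cohort",
    "simulate_snapshot",
    "simulate_marker_durations",
    "apply_ly",
]

#: reference constants from the earlier clonal-data model of the same system,
#: used for reporting comparisons only (never as simulation inputs)
REFERENCE_CONSTANTS = {
    "gamma_reservoir": 0.007,
    "gamma_operational": 0.023,
    "reservoir_fraction": 0.61,
}


@dataclass(frozen=True)
class SimulationParams:
    """All tunable parameters of the lineage simulator (rates per day, areas in um^2)."""

    # activation hazards of quiescent cells
    gamma_neg: float = 0.0056
    gamma_pos: float = 0.0246
    #: log-odds slope of the area modulation of the activation hazard (0 = off)
    area_coupling: float = 0.0
    area_ref_neg: float = 112.0
    area_ref_pos: float = 54.0
    #: activation-onset -> cytokinesis rate
    lambda_act: float = 0.326
    # multiplicative area growth of quiescent cells
    growth_neg: float = math.log(1.3) / 40.0
    growth_pos: float = 0.0
    # delamination rule
    delam_area_threshold: float = 10.0
    delam_requires_pos: bool = True
    # initial-area distributions (mean, sd) -> lognormal
    area_qnsc: tuple[float, float] = (84.0, 8.9)
    area_ansc: tuple[float, float] = (54.0, 17.1)
    area_anp: tuple[float, float] = (10.0, 3.6)
    area_qnsc_neg: tuple[float, float] = (112.0, 15.4)
    area_qnsc_pos: tuple[float, float] = (54.0, 3.7)
    area_ansc_neg: tuple[float, float] = (91.0, 28.2)
    area_ansc_pos: tuple[float, float] = (32.0, 8.3)
    #: fraction of root NSCs that are deltaA-positive (80/20 split)
    frac_pos_initial: float = 0.20
    #: SD of the relative daughter-area imbalance x in areas A(1+-x)/2;
    #: 0.212 puts ~60% of pairs above a 20% area difference
    division_asym_noise: float = 0.212
    #: probability the positive daughter of a negative mother is already
    #: scored ON at DC (else at DC+1)
    fate_on_at_dc_prob: float = 0.7
    #: fraction of positive/positive daughter pairs that later convert to a
    #: binary ON/OFF pair, and the mean (days) of the exponential lag
    pospos_binary_frac: float = 0.05
    pospos_binary_lag_mean: float = 11.5
    # per-track per-movie deltaA switch rates in never-dividing tracks
    switch_off_rate: float = 9 / 703
    switch_on_rate: float = 5 / 703
    # probability a daughter returns to quiescence (vs dividing reiteratively)
    requiescence_prob_pos: float = 223 / 250
    requiescence_prob_neg: float = 223 / 250
    # imaging design
    imaging_gaps: tuple[float, ...] = (2.0, 3.0)
    imaging_days: Optional[tuple[float, ...]] = None
    movie_days: float = 43.0
    #: multiplicative lognormal measurement noise SD on observed areas
    measure_noise: float = 0.05
    # Notch-blockade mode: published per-cell-per-day division likelihood
    # over the 4-day assay; converted internally to a hazard
    ly_rate: float = 0.0852
    ly_assay_days: float = 4.0
    ly_start_day: Optional[float] = None
    n_fish: int = 4
    # snapshot mixtures
    snapshot_state_fracs: tuple[float, float, float] = (0.76, 0.09, 0.15)
    snapshot_pos_fracs: tuple[float, float, float] = (0.23, 0.87, 0.99)

    def validate(self) -> None:
        for name in (
            "gamma_neg",
            "gamma_pos",
            "area_coupling",
            "lambda_act",
            "growth_neg",
            "growth_pos",
            "switch_off_rate",
            "switch_on_rate",
            "ly_rate",
            "measure_noise",
            "division_asym_noise",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in (
            "frac_pos_initial",
            "fate_on_at_dc_prob",
            "pospos_binary_frac",
            "requiescence_prob_pos",
            "requiescence_prob_neg",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        for name in ("area_qnsc", "area_ansc", "area_anp", "area_qnsc_neg",
                     "area_qnsc_pos", "area_ansc_neg", "area_ansc_pos"):
            m, s = getattr(self, name)
            if m <= 0 or s < 0:
                raise ValidationError(f"{name} must have positive mean, sd >= 0")
        if any(g <= 0 for g in self.imaging_gaps):
            raise ValidationError("imaging gaps must be positive")
        if abs(sum(self.snapshot_state_fracs) - 1) > 1e-9:
            raise ValidationError("snapshot_state_fracs must sum to 1")
        if not all(0 <= f <= 1 for f in self.snapshot_pos_fracs):
            raise ValidationError("snapshot_pos_fracs must lie in [0, 1]")
        if self.ly_rate * self.ly_assay_days >= 1:
            raise ValidationError(
                "ly_rate * ly_assay_days must be < 1 for the hazard conversion"
            )

    @property
    def ly_hazard(self) -> float:
        """Internal LY activation hazard reproducing ``ly_rate`` under the
        naive divisions/(tracks*days) estimator over the assay window."""
        return -math.log1p(-self.ly_rate * self.ly_assay_days) / self.ly_assay_days


def apply_ly(params: SimulationParams, start_day: float) -> SimulationParams:
    """Switch the simulation into Notch-blockade mode from ``start_day``.

    From that day on both deltaA statuses share one elevated activation
    hazard (derived from ``ly_rate``) while the area coupling is retained;
    cytokinesis follows at the next imaging time point and division fate
    rules are unchanged.
    """
    if not 0 <= start_day <= params.movie_days:
        raise ValidationError("ly start_day must lie within the movie")
    return replace(params, ly_start_day=start_day)


def imaging_grid(params: SimulationParams) -> np.ndarray:
    """Imaging days: either an explicit list or alternating gaps from day 0."""
    if params.imaging_days is not None:
        days = np.asarray(params.imaging_days, dtype=float)
        if not np.all(np.diff(days) > 0):
            raise ValidationError("imaging_days must be strictly increasing")
        return days
    days = [0.0]
    i = 0
    while True:
        nxt = days[-1] + params.imaging_gaps[i % len(params.imaging_gaps)]
        if nxt > params.movie_days + 1e-9:
            break
        days.append(nxt)
        i += 1
    return np.asarray(days)


@dataclass
class GroundTruth:
    """Exact event log of a simulated cohort, for oracle tests."""

    divisions: pd.DataFrame
    delaminations: pd.DataFrame
    switches: pd.DataFrame
    #: activation records: onset day, true cytokinesis time (NaN if censored)
    activations: pd.DataFrame
    #: per-track true (noise-free) areas, keyed (track_id, tp_index)
    true_areas: dict[tuple[str, int], float]


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size=None):
    if sd == 0:
        return np.full(size, mean) if size is not None else mean
    s2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - s2 / 2
    return rng.lognormal(mu, math.sqrt(s2), size)


class _Cell:
    __slots__ = (
        "track_id", "fish_id", "parent_id", "birth_idx", "area", "score",
        "on_score", "on_from_idx", "off_from_idx", "reiterative", "generation",
    )

    def __init__(self, track_id, fish_id, parent_id, birth_idx, area, score,
                 on_score=0, on_from_idx=None, off_from_idx=None,
                 reiterative=False, generation=0):
        self.track_id = track_id
        self.fish_id = fish_id
        self.parent_id = parent_id
        self.birth_idx = birth_idx
        self.area = area            # true area at birth
        self.score = score          # deltaA intensity score before any switch
        self.on_score = on_score    # score acquired at on_from_idx
        self.on_from_idx = on_from_idx    # grid index from which score turns positive
        self.off_from_idx = off_from_idx  # grid index from which score turns 0
        self.reiterative = reiterative
        self.generation = generation

    def score_at(self, idx: int) -> int:
        s = self.score
        if self.on_from_idx is not None and idx >= self.on_from_idx:
            s = self.on_score
        if self.off_from_idx is not None and idx >= self.off_from_idx:
            s = 0
        return s


def _draw_pos_score(rng: np.random.Generator) -> int:
    return int(rng.choice([1, 2, 3], p=[0.3, 0.4, 0.3]))


def simulate_cohort(
    params: SimulationParams, n_tracks: int, seed: int
) -> LineageForest:
    """Simulate ``n_tracks`` root NSC tracks on the imaging grid.

    Returns a validated :class:`LineageForest` whose ``truth`` attribute
    holds the generator's exact event log (:class:`GroundTruth`).
    Deterministic given (params, n_tracks, seed).
    """
    if n_tracks < 1:
        raise ValidationError("n_tracks must be >= 1")
    params.validate()
    rng = np.random.default_rng(seed)
    grid = imaging_grid(params)
    n_tp = len(grid)
    treatment = Treatment.LY if params.ly_start_day is not None and \
        params.ly_start_day <= grid[0] else Treatment.CONTROL

    forest = LineageForest()
    div_log, delam_log, switch_log, act_log = [], [], [], []
    true_areas: dict[tuple[str, int], float] = {}

    queue: list[_Cell] = []
    for i in range(n_tracks):
        fish = f"fish{i % params.n_fish + 1}"
        pos = rng.random() < params.frac_pos_initial
        mean, sd = params.area_qnsc_pos if pos else params.area_qnsc_neg
        area = float(_lognormal(rng, mean, sd))
        score = _draw_pos_score(rng) if pos else 0
        queue.append(_Cell(f"{fish}-t{i:04d}", fish, None, 0, area, score))

    while queue:
        cell = queue.pop(0)
        track = _simulate_cell(
            cell, params, grid, rng, forest, queue,
            div_log, delam_log, act_log, true_areas,
        )
        forest.add(track)

    _apply_nondivider_switches(forest, params, grid, rng, switch_log, true_areas)

    forest.truth = GroundTruth(
        divisions=pd.DataFrame(
            div_log,
            columns=[
                "mother_id", "daughter1_id", "daughter2_id", "division_tp",
                "division_day", "onset_day", "cytokinesis_time",
                "mother_status", "mother_area_true", "from_quiescence",
                "asymmetric_fate", "pospos_convert_idx",
            ],
        ),
        delaminations=pd.DataFrame(
            delam_log, columns=["track_id", "tp_index", "area_true", "delta_positive"]
        ),
        switches=pd.DataFrame(switch_log, columns=["track_id", "direction", "tp_index"]),
        activations=pd.DataFrame(
            act_log,
            columns=["track_id", "onset_day", "cytokinesis_time", "observed_division"],
        ),
        true_areas=true_areas,
    )
    gaps = None  # the simulator's own grid may mix gap lengths (LY assay)
    forest.validate(allowed_gaps=gaps)
    return forest


def _hazard(params: SimulationParams, pos: bool, area: float, day: float) -> float:
    ly = params.ly_start_day is not None and day >= params.ly_start_day - 1e-9
    base = params.ly_hazard if ly else (params.gamma_pos if pos else params.gamma_neg)
    if params.area_coupling == 0:
        return base
    ref = params.area_ref_pos if pos else params.area_ref_neg
    return base * 2.0 / (1.0 + math.exp(-params.area_coupling * (area - ref)))


def _growth(params: SimulationParams, pos: bool) -> float:
    return params.growth_pos if pos else params.growth_neg


def _simulate_cell(cell, params, grid, rng, forest, queue,
                   div_log, delam_log, act_log, true_areas):
    """Advance one cell from birth to division/delamination/censoring."""
    n_tp = len(grid)
    points: list[TrackPoint] = []
    area = cell.area
    onset: Optional[float] = None
    div_time: Optional[float] = None

    if cell.reiterative:
        onset = float(grid[cell.birth_idx])
        ly = params.ly_start_day is not None and onset >= params.ly_start_day - 1e-9
        # under Notch blockade cytokinesis lands on the next imaging tp
        delay = 1e-6 if ly else float(rng.exponential(1.0 / params.lambda_act))
        div_time = onset + delay

    idx = cell.birth_idx
    last_event = Event.NONE
    while idx < n_tp:
        day = float(grid[idx])
        pos = cell.score_at(idx) >= 1
        # division reached before this observation?
        if div_time is not None and div_time <= day + 1e-12:
            last_event = Event.DIVISION
            # mother's final recorded point is the previous grid day; the
            # division flag is set on it below
            break
        true_areas[(cell.track_id, idx)] = area
        marker = onset is not None and day >= onset - 1e-12
        obs_area = area * math.exp(rng.normal(0.0, params.measure_noise)) \
            if params.measure_noise > 0 else area
        points.append(TrackPoint(
            tp_index=idx, day=day, area=obs_area,
            delta_score=cell.score_at(idx), marker_on=bool(marker),
        ))
        # delamination of small deltaA-positive cells
        if area < params.delam_area_threshold and (pos or not params.delam_requires_pos):
            last_event = Event.DELAMINATION
            delam_log.append((cell.track_id, idx, area, pos))
            break
        if idx == n_tp - 1:
            break
        gap = float(grid[idx + 1] - grid[idx])
        if onset is None:
            rate = _hazard(params, pos, area, day)
            p_act = 1.0 - math.exp(-rate * gap)
            if rng.random() < p_act:
                onset = day + float(rng.uniform(0.0, gap))
                ly = params.ly_start_day is not None and \
                    onset >= params.ly_start_day - 1e-9
                delay = 0.0 if ly else float(rng.exponential(1.0 / params.lambda_act))
                div_time = onset + delay
            else:
                area *= math.exp(_growth(params, pos) * gap)
        # after onset the apical area is frozen until cytokinesis
        idx += 1

    if not points:
        # degenerate: division before the first observation of a reiterative
        # daughter cannot happen (div_time >= birth day); delamination at
        # birth leaves one point; guard anyway
        raise ValidationError(f"track {cell.track_id}: no observable points")

    if last_event is Event.DIVISION:
        points[-1] = replace(points[-1], event=Event.DIVISION)
        div_idx = points[-1].tp_index + 1  # daughters' first grid index
        _spawn_daughters(cell, points, div_idx, area, onset, div_time, params,
                         grid, rng, queue, div_log, act_log)
        act_log.append((cell.track_id, onset, div_time, True))
    elif last_event is Event.DELAMINATION:
        points[-1] = replace(points[-1], event=Event.DELAMINATION)
    elif onset is not None:
        # activated but censored by movie end
        act_log.append((cell.track_id, onset, div_time, False))

    return Track(
        track_id=cell.track_id, fish_id=cell.fish_id,
        treatment=_treatment_of(params, grid), parent_id=cell.parent_id,
        points=points,
    )


def _treatment_of(params: SimulationParams, grid) -> Treatment:
    if params.ly_start_day is not None and params.ly_start_day <= grid[0] + 1e-9:
        return Treatment.LY
    return Treatment.CONTROL


def _spawn_daughters(cell, points, div_idx, area, onset, div_time, params,
                     grid, rng, queue, div_log, act_log):
    """Split the mother at grid index ``div_idx`` and enqueue two daughters."""
    mother_pos = cell.score_at(points[-1].tp_index) >= 1
    # relative imbalance, truncated to keep both areas positive
    for _ in range(100):
        x = float(rng.normal(0.0, params.division_asym_noise))
        if abs(x) < 0.95:
            break
    else:
        raise ValidationError("could not draw a valid daughter-area imbalance")
    a1 = area * (1 + x) / 2
    a2 = area * (1 - x) / 2

    d1_id = cell.track_id + ".1"
    d2_id = cell.track_id + ".2"
    convert_idx = None
    if mother_pos:
        # two positive daughters with unequal scores; a small fraction of
        # pairs later converts to a binary ON/OFF pair
        lo = int(rng.integers(1, 3))           # 1 or 2
        hi = int(rng.integers(lo + 1, 4))      # strictly higher
        s1, s2 = (hi, lo) if rng.random() < 0.5 else (lo, hi)
        off1 = off2 = None
        if rng.random() < params.pospos_binary_frac:
            lag = float(rng.exponential(params.pospos_binary_lag_mean))
            t_conv = grid[div_idx] + lag
            later = np.searchsorted(grid, t_conv - 1e-12)
            if later < len(grid):
                convert_idx = int(later)
                if s1 < s2:
                    off1 = convert_idx
                else:
                    off2 = convert_idx
        k1 = _Cell(d1_id, cell.fish_id, cell.track_id, div_idx, a1, s1,
                   off_from_idx=off1, generation=cell.generation + 1)
        k2 = _Cell(d2_id, cell.fish_id, cell.track_id, div_idx, a2, s2,
                   off_from_idx=off2, generation=cell.generation + 1)
    else:
        # binary asymmetric fate: one daughter stays negative forever, the
        # other acquires the reporter at DC or DC+1
        on_score = _draw_pos_score(rng)
        on_at_dc = rng.random() < params.fate_on_at_dc_prob
        on_idx = div_idx if on_at_dc else div_idx + 1
        gen = cell.generation + 1
        on_kwargs = dict(on_score=on_score, on_from_idx=on_idx, generation=gen)
        if rng.random() < 0.5:
            k1 = _Cell(d1_id, cell.fish_id, cell.track_id, div_idx, a1, 0, **on_kwargs)
            k2 = _Cell(d2_id, cell.fish_id, cell.track_id, div_idx, a2, 0,
                       generation=gen)
        else:
            k1 = _Cell(d1_id, cell.fish_id, cell.track_id, div_idx, a1, 0,
                       generation=gen)
            k2 = _Cell(d2_id, cell.fish_id, cell.track_id, div_idx, a2, 0, **on_kwargs)

    for k in (k1, k2):
        k_pos_at_birth = k.score_at(k.birth_idx) >= 1
        p_req = params.requiescence_prob_pos if k_pos_at_birth \
            else params.requiescence_prob_neg
        k.reiterative = rng.random() >= p_req
        queue.append(k)

    # the rule-based from-quiescence flag: at least two division-free
    # imaging intervals observed before the division
    from_quiescence = (points[-1].tp_index - points[0].tp_index) >= 2
    div_log.append((
        cell.track_id, d1_id, d2_id, points[-1].tp_index, float(grid[div_idx]),
        onset, div_time, mother_pos, area, from_quiescence,
        not mother_pos, convert_idx,
    ))


def _apply_nondivider_switches(forest, params, grid, rng, switch_log, true_areas):
    """Rare deltaA switches in root tracks that never divide nor delaminate."""
    children = forest.children_map()
    for track in sorted(forest, key=lambda t: t.track_id):
        if track.parent_id is not None or track.track_id in children:
            continue
        if track.terminal_event is not Event.NONE or len(track.points) < 3:
            continue
        pos = any(s for s in track.statuses())
        if pos and rng.random() < params.switch_off_rate:
            tp = int(rng.integers(1, len(track.points)))
            for i in range(tp, len(track.points)):
                track.points[i] = replace(track.points[i], delta_score=0)
            switch_log.append((track.track_id, "off", track.points[tp].tp_index))
        elif not pos and rng.random() < params.switch_on_rate:
            tp = int(rng.integers(1, len(track.points)))
            score = _draw_pos_score(rng)
            for i in range(tp, len(track.points)):
                track.points[i] = replace(track.points[i], delta_score=score)
            switch_log.append((track.track_id, "on", track.points[tp].tp_index))


# ---------------------------------------------------------------------------
# static snapshots
# ---------------------------------------------------------------------------


def simulate_snapshot(
    params: SimulationParams, n_cells: int, seed: int, n_hemispheres: int = 4
) -> pd.DataFrame:
    """Simulate a fixed-tissue style cell table.

    States are drawn from ``snapshot_state_fracs`` (qNSC, aNSC singlet, aNP),
    apical areas from the per-state lognormal distributions, and deltaA
    positivity independently at the per-state fractions.  Per-state area
    means/SDs and deltaA fractions converge to the configured values as
    ``n_cells`` grows.
    """
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    params.validate()
    rng = np.random.default_rng(seed)
    states = [SnapshotState.QNSC, SnapshotState.ANSC_SINGLET, SnapshotState.ANP]
    dists = {
        SnapshotState.QNSC: params.area_qnsc,
        SnapshotState.ANSC_SINGLET: params.area_ansc,
        SnapshotState.ANP: params.area_anp,
    }
    pos_frac = dict(zip(states, params.snapshot_pos_fracs))
    draw = rng.choice(len(states), size=n_cells, p=params.snapshot_state_fracs)
    rows = []
    for i in range(n_cells):
        state = states[draw[i]]
        mean, sd = dists[state]
        area = float(_lognormal(rng, mean, sd))
        for _ in range(100):
            if area > 0:
                break
            area = float(_lognormal(rng, mean, sd))
        else:
            raise ValidationError("could not draw a positive area")
        rows.append({
            "hemisphere_id": f"hemi{i % n_hemispheres + 1}",
            "cell_id": f"c{i:05d}",
            "state": state.value,
            "area_um2": area,
            "delta_positive": bool(rng.random() < pos_frac[state]),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stand-alone marker-timing simulation
# ---------------------------------------------------------------------------


def simulate_marker_durations(
    rate: float,
    n: int,
    seed: int,
    gaps: Sequence[float] = (2.0, 3.0),
    movie_days: float = 43.0,
):
    """Draw activation-onset -> cytokinesis durations and censor them onto an
    imaging grid, emulating the marker-timing calibration experiment.

    Onsets are uniform over the movie; durations are Exponential(``rate``).
    Each duration is recorded only at the resolution of the imaging design:
    completed durations are bracketed by the grid partition (the interval
    [t_k, t_k+1) of the alternating 2/3-day grid that contains them), and a
    duration still running at the movie end is right-censored at the
    remaining observation time.  Returns ``(durations, true_durations)``
    with :class:`nsctrack.timing.CensoredDuration` entries.
    """
    from .timing import CensoredDuration

    if rate <= 0:
        raise ValidationError("rate must be > 0")
    rng = np.random.default_rng(seed)
    grid = imaging_grid(SimulationParams(imaging_gaps=tuple(gaps), movie_days=movie_days))
    last = float(grid[-1])
    durations, truths = [], []
    while len(durations) < n:
        onset = float(rng.uniform(0.0, last))
        t = float(rng.exponential(1.0 / rate))
        remaining = last - onset
        if t > remaining:
            # still undivided at the movie end
            if remaining > 0:
                durations.append(CensoredDuration(remaining, math.inf))
                truths.append(t)
            continue
        k = int(np.searchsorted(grid, t, side="right"))  # first grid day > t
        lower = float(grid[k - 1])
        upper = float(grid[k]) if k < len(grid) else math.inf
        if not upper > lower:
            continue
        durations.append(CensoredDuration(lower, upper))
        truths.append(t)
    return durations, truths
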
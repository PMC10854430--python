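"""Descriptive and rate statistics for NSC lineage tracks.

Covers apical-area growth curves during quiescence, exponential growth rates
and doubling times, per-cell-per-day division likelihoods with exact Poisson
confidence intervals, per-fish division frequencies, area conservation at
cytokinesis, and snapshot summaries with Mann-Whitney comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import (
    DELTA_POS_THRESHOLD,
    Event,
    LineageForest,
    RateEstimate,
    Track,
    ValidationError,
)
from .annotate import DivisionEvent

__all__ = [
    "GrowthCurve",
    "normalized_growth",
    "doubling_time",
    "division_likelihood",
    "division_likelihood_from_forest",
    "division_frequency_per_track",
    "area_conservation",
    "snapshot_summary",
]

BOOTSTRAP_RESAMPLES = 1000
#: groups up to this size use the exact Mann-Whitney null distribution
MWU_EXACT_MAX_N = 20


@dataclass
class GrowthCurve:
    """Median normalized apical area per imaging day with bootstrap 95% CI."""

    day_bins: np.ndarray
    median_normalized_area: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_per_bin: np.ndarray
    fitted_rate: RateEstimate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.day_bins,
                "median_normalized_area": self.median_normalized_area,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "n": self.n_per_bin,
            }
        )


def normalized_growth(
    tracks: Iterable[Track],
    n_boot: int = BOOTSTRAP_RESAMPLES,
    seed: int = 0,
) -> GrowthCurve:
    """Growth curve of nondividing tracks, each normalized to its first area.

    Day bins snap to the union of observed imaging days (no interpolation).
    The per-bin 95% CI is a seeded percentile bootstrap of the median; the
    fitted rate comes from a log-linear fit of the per-bin medians against
    day, with a bootstrap percentile CI on the slope.
    """
    series = []
    for t in tracks:
        if t.terminal_event is Event.DIVISION:
            raise ValidationError(f"track {t.track_id}: dividing track in growth set")
        pts = [(p.day - t.first_day, p.area) for p in t.points if p.area is not None]
        if not pts:
            continue
        a0 = pts[0][1]
        series.append([(d, a / a0) for d, a in pts])
    if not series:
        raise ValidationError("no tracks with observed areas")

    by_day: dict[float, list[float]] = {}
    for s in series:
        for d, v in s:
            by_day.setdefault(round(d, 6), []).append(v)
    days = np.array(sorted(by_day))
    values = [np.asarray(by_day[d]) for d in days]
    med = np.array([np.median(v) for v in values])
    n = np.array([len(v) for v in values])

    rng = np.random.default_rng(seed)
    lo = np.empty_like(med)
    hi = np.empty_like(med)
    boot_slopes = np.empty(n_boot)
    boot_meds = np.empty((n_boot, len(days)))
    for b in range(n_boot):
        for j, v in enumerate(values):
            boot_meds[b, j] = np.median(rng.choice(v, size=len(v), replace=True))
    lo = np.percentile(boot_meds, 2.5, axis=0)
    hi = np.percentile(boot_meds, 97.5, axis=0)

    pos = med > 0
    slope = np.polyfit(days[pos], np.log(med[pos]), 1)[0]
    for b in range(n_boot):
        bm = boot_meds[b]
        ok = bm > 0
        boot_slopes[b] = np.polyfit(days[ok], np.log(bm[ok]), 1)[0]
    s_lo, s_hi = np.percentile(boot_slopes, [2.5, 97.5])
    # a flat curve can bootstrap to a degenerate slope CI; keep it bracketing
    s_lo, s_hi = min(s_lo, slope), max(s_hi, slope)
    fitted = RateEstimate(
        rate=max(slope, 0.0), ci_low=min(s_lo, slope), ci_high=max(s_hi, slope),
        n_events=len(series),
    )
    return GrowthCurve(
        day_bins=days, median_normalized_area=med, ci_low=lo, ci_high=hi,
        n_per_bin=n, fitted_rate=fitted,
    )


def doubling_time(rate: float) -> float:
    """Days needed to double at exponential per-day ``rate`` (ln 2 / rate)."""
    if rate <= 0:
        raise ValidationError(f"rate must be > 0, got {rate}")
    return math.log(2) / rate


def division_likelihood(n_divisions: int, n_tracks: int, days: float) -> RateEstimate:
    """Per-cell-per-day division likelihood with an exact Poisson 95% CI.

    Point estimate ``n_divisions / (n_tracks * days)``; the CI is the exact
    (Garwood) Poisson interval on the event count divided by the exposure.
    With zero events the interval is one-sided from zero.
    """
    if n_divisions < 0:
        raise ValidationError("n_divisions must be >= 0")
    if n_tracks <= 0 or days <= 0:
        raise ValidationError("n_tracks and days must be > 0")
    exposure = n_tracks * days
    rate = n_divisions / exposure
    if n_divisions == 0:
        lo = 0.0
    else:
        lo = sps.chi2.ppf(0.025, 2 * n_divisions) / 2 / exposure
    hi = sps.chi2.ppf(0.975, 2 * n_divisions + 2) / 2 / exposure
    return RateEstimate(rate=rate, ci_low=lo, ci_high=hi, n_events=n_divisions)


def division_likelihood_from_forest(
    forest: LineageForest, from_quiescence_only: bool = False,
    min_quiet_intervals: int = 2,
) -> RateEstimate:
    """Division likelihood with per-track risk time as the exposure.

    Each track contributes its observed days until division (or until its
    last observation); divisions are terminal division events.  This is the
    survival-style estimator, unbiased for the underlying hazard when the
    per-movie division probability is not small.
    """
    n_div = 0
    exposure = 0.0
    for t in forest:
        exposure += t.last_day - t.first_day
        if t.terminal_event is Event.DIVISION:
            if not from_quiescence_only or t.n_intervals >= min_quiet_intervals:
                n_div += 1
    if exposure <= 0:
        raise ValidationError("no positive exposure in forest")
    return division_likelihood(n_div, 1, exposure)


def division_frequency_per_track(
    forest: LineageForest,
    events: Sequence[DivisionEvent],
    status_filter: Optional[bool] = None,
    threshold: int = DELTA_POS_THRESHOLD,
    roots_only: bool = True,
) -> tuple[float, float, pd.DataFrame]:
    """Per-fish percentage of tracks with a from-quiescence division.

    Returns (mean %, SEM %, per-fish table).  ``status_filter`` restricts to
    tracks whose most prevalent deltaA status matches (True = positive).
    Fish with zero eligible tracks are excluded.
    """
    divided = {e.mother_track for e in events if e.from_quiescence}
    per_fish: dict[str, list[bool]] = {}
    for t in forest:
        if roots_only and t.parent_id is not None:
            continue
        if status_filter is not None:
            statuses = t.statuses(threshold)
            if not statuses:
                continue
            prevalent = sum(statuses) * 2 >= len(statuses)
            if prevalent != status_filter:
                continue
        per_fish.setdefault(t.fish_id, []).append(t.track_id in divided)
    rows = [
        {"fish_id": f, "n_tracks": len(v), "pct_divided": 100.0 * np.mean(v)}
        for f, v in sorted(per_fish.items())
        if len(v) > 0
    ]
    table = pd.DataFrame(rows, columns=["fish_id", "n_tracks", "pct_divided"])
    if table.empty:
        raise ValidationError("no eligible tracks")
    pct = table["pct_divided"].to_numpy()
    sem = float(pct.std(ddof=1) / math.sqrt(len(pct))) if len(pct) > 1 else 0.0
    return float(pct.mean()), sem, table


def area_conservation(
    events: Sequence[DivisionEvent], forest: LineageForest
) -> tuple[pd.DataFrame, dict]:
    """Per-division ratio (sum of DC areas) / (MC area), plus a summary.

    Events with a missing mother or daughter area are skipped and counted.
    """
    rows = []
    skipped = 0
    for e in events:
        if e.mother_area is None:
            skipped += 1
            continue
        dareas = []
        for did in e.daughter_tracks:
            a = forest[did].points[0].area
            if a is None:
                break
            dareas.append(a)
        if len(dareas) != 2:
            skipped += 1
            continue
        rows.append(
            {"mother_track": e.mother_track, "ratio": sum(dareas) / e.mother_area}
        )
    table = pd.DataFrame(rows, columns=["mother_track", "ratio"])
    if table.empty:
        summary = {"n": 0, "skipped": skipped}
    else:
        r = table["ratio"]
        summary = {
            "n": len(r),
            "skipped": skipped,
            "median": float(r.median()),
            "iqr": (float(r.quantile(0.25)), float(r.quantile(0.75))),
        }
    return table, summary


def snapshot_summary(
    cells: pd.DataFrame,
    group_col: str = "state",
    value_col: str = "area_um2",
    exact_max_n: int = MWU_EXACT_MAX_N,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group summary and pairwise two-sided Mann-Whitney U tests.

    U statistics use midranks for ties; groups with both sizes at or below
    ``exact_max_n`` use the exact null distribution, larger comparisons the
    tie-corrected normal approximation.  Empty groups are excluded.
    """
    groups = {
        g: sub[value_col].to_numpy()
        for g, sub in cells.groupby(group_col)
        if len(sub) > 0
    }
    if len(groups) < 2:
        raise ValidationError("need at least two nonempty groups")
    summary = pd.DataFrame(
        [
            {
                group_col: g,
                "n": len(v),
                "mean": float(np.mean(v)),
                "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
                "median": float(np.median(v)),
            }
            for g, v in sorted(groups.items())
        ]
    )
    names = sorted(groups)
    tests = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            va, vb = groups[a], groups[b]
            method = "exact" if max(len(va), len(vb)) <= exact_max_n else "asymptotic"
            res = sps.mannwhitneyu(va, vb, alternative="two-sided", method=method)
            tests.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "U": float(res.statistic),
                    "p": float(res.pvalue),
                    "method": method,
                }
            )
    return summary, pd.DataFrame(tests)
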
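import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

from nsctrack.model import Event, LineageForest, Track, TrackPoint, Treatment
from nsctrack.simulate import SimulationParams, simulate_cohort
from nsctrack.annotate import detect_divisions


def make_track(track_id, days, areas=None, scores=None, markers=None, event=None,
               fish="fish1", parent=None, first_tp=0, treatment=Treatment.CONTROL):
    """Small helper to build a track from parallel per-point lists."""
    n = len(days)
    areas = areas if areas is not None else [100.0] * n
    scores = scores if scores is not None else [0] * n
    markers = markers if markers is not None else [False] * n
    points = []
    for i in range(n):
        ev = Event(event) if (event and i == n - 1) else Event.NONE
        points.append(
            TrackPoint(
                tp_index=first_tp + i,
                day=days[i],
                area=areas[i],
                delta_score=scores[i],
                marker_on=markers[i],
                event=ev,
            )
        )
    return Track(track_id=track_id, fish_id=fish, treatment=treatment,
                 parent_id=parent, points=points)


@pytest.fixture()
def toy_division_forest():
    """Mother dividing after a long quiescent phase, two daughters of
    opposite deltaA status, one delaminating elsewhere."""
    f = LineageForest()
    days = [0, 2, 5, 7, 10, 12]
    f.add(make_track("m", days, areas=[100, 101, 102, 103, 104, 105],
                     scores=[0] * 6, markers=[False, False, False, False, True, True],
                     event="division"))
    f.add(make_track("m.1", [15, 17, 20, 22, 25, 27, 30], areas=[52] * 7,
                     scores=[0] * 7, parent="m", first_tp=6))
    f.add(make_track("m.2", [15, 17, 20, 22, 25, 27, 30], areas=[53] * 7,
                     scores=[2] * 7, parent="m", first_tp=6))
    f.add(make_track("q", [0, 2, 5, 7, 10, 12, 15, 17, 20, 22, 25, 27, 30],
                     areas=[80 + i for i in range(13)], scores=[1] * 13))
    f.validate()
    return f


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter cohort at the study scale, shared across tests."""
    return simulate_cohort(SimulationParams(), 828, 5)


@pytest.fixture(scope="session")
def default_events(default_cohort):
    return detect_divisions(default_cohort)
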
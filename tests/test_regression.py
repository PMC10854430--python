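"""Division-propensity logistic model, type II Wald tests, window rescaling,
and the division-fate multinomial model."""

import math
import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from nsctrack.model import LineageForest
from nsctrack.simulate import SimulationParams, simulate_cohort
from nsctrack.annotate import detect_divisions
from nsctrack.regression import (
    SeparationError,
    build_regression_table,
    fate_probabilities,
    fit_division_logistic,
    fit_fate_multinomial,
    predicted_division_curve,
    rescale_probability,
    wald_type2,
)

from conftest import make_track


# ---------------------------------------------------------------------------
# regression table construction
# ---------------------------------------------------------------------------


def _table_forest():
    f = LineageForest()
    grid = [0, 2, 5, 7, 10, 12, 15, 17, 20]
    # divider: area taken at the last pre-division point
    f.add(make_track("d1", grid[:3], areas=[100, 90, 80], scores=[0, 0, 0],
                     event="division"))
    f.add(make_track("d1.1", grid[3:9], areas=[40] * 6, scores=[0] * 6,
                     parent="d1", first_tp=3))
    f.add(make_track("d1.2", grid[3:9], areas=[40] * 6, scores=[2] * 6,
                     parent="d1", first_tp=3))
    # nondividers: average area, most prevalent status
    f.add(make_track("n1", grid[:3], areas=[100, 110, 120], scores=[0, 0, 1]))
    f.add(make_track("n2", grid[:3], areas=[60, 60, 60], scores=[2, 2, 0]))
    f.validate()
    return f


def test_regression_rows_use_pre_division_and_average_covariates():
    f = _table_forest()
    table = build_regression_table(f, detect_divisions(f))
    rows = table.set_index("track_id")
    assert rows.loc["d1", "divided"]
    assert rows.loc["d1", "area"] == 80.0
    assert rows.loc["d1", "fate"] == "neg_pos"
    assert not rows.loc["n1", "divided"]
    assert rows.loc["n1", "area"] == pytest.approx(110.0)
    assert rows.loc["n1", "delta_pos"] == False  # most prevalent of [0,0,1]
    assert rows.loc["n2", "delta_pos"] == True
    assert rows.loc["n1", "fate"] is None
    # daughters are not rows of their own
    assert "d1.1" not in rows.index


def test_regression_table_is_deterministic(default_cohort, default_events):
    a = build_regression_table(default_cohort, default_events)
    b = build_regression_table(default_cohort, default_events)
    pd.testing.assert_frame_equal(a, b)
    assert a.attrs["excluded"] == 0


# ---------------------------------------------------------------------------
# logistic fit
# ---------------------------------------------------------------------------


def _two_group_table():
    rows = []
    for i in range(10):
        rows.append({"track_id": f"a{i}", "fish_id": "f1", "treatment": "control",
                     "divided": i < 8, "area": 50.0, "delta_pos": True, "fate": None})
    for i in range(10):
        rows.append({"track_id": f"b{i}", "fish_id": "f1", "treatment": "control",
                     "divided": i < 2, "area": 50.0, "delta_pos": False, "fate": None})
    return pd.DataFrame(rows)


def test_logistic_two_by_two_closed_form():
    """Saturated 2x2 MLE: intercept = logit(0.2), coefficient =
    logit(0.8) - logit(0.2)."""
    fit = fit_division_logistic(_two_group_table(), "divided ~ delta_pos")
    assert fit.params["Intercept"] == pytest.approx(math.log(0.2 / 0.8), abs=1e-3)
    assert fit.params["delta_pos"] == pytest.approx(
        math.log(0.8 / 0.2) - math.log(0.2 / 0.8), abs=1e-3
    )


def test_single_class_outcome_raises_separation():
    t = _two_group_table()
    t["divided"] = False
    with pytest.raises(SeparationError):
        fit_division_logistic(t, "divided ~ delta_pos")


def test_perfectly_separating_covariate_raises():
    rows = pd.DataFrame({
        "track_id": [str(i) for i in range(20)],
        "fish_id": "f1", "treatment": "control",
        "area": np.r_[np.linspace(10, 40, 10), np.linspace(60, 90, 10)],
        "divided": [False] * 10 + [True] * 10,
        "delta_pos": False, "fate": None,
    })
    with pytest.raises(SeparationError):
        fit_division_logistic(rows, "divided ~ area")


def test_area_coefficient_recovered_from_known_law():
    rng = np.random.default_rng(5)
    n = 2000
    area = rng.uniform(10, 150, n)
    beta = 0.02
    p = 1 / (1 + np.exp(-(-2.5 + beta * area)))
    table = pd.DataFrame({
        "track_id": [str(i) for i in range(n)],
        "fish_id": "f1", "treatment": "control",
        "divided": rng.random(n) < p,
        "area": area, "delta_pos": False, "fate": None,
    })
    fit = fit_division_logistic(table, "divided ~ area")
    se = math.sqrt(fit.cov.loc["area", "area"])
    assert abs(fit.params["area"] - beta) < 1.96 * se


def test_predicted_probability_monotone_in_area(default_cohort, default_events):
    params = SimulationParams(area_coupling=0.05, gamma_neg=0.01, gamma_pos=0.03)
    forest = simulate_cohort(params, 1000, seed=15)
    table = build_regression_table(forest, detect_divisions(forest))
    fit = fit_division_logistic(table, "divided ~ area + delta_pos")
    if fit.params["area"] > 0:
        grid = np.linspace(20, 150, 10)
        curve = predicted_division_curve(fit, grid, delta_pos=False)
        assert (np.diff(curve["p_divide"]) > 0).all()


# ---------------------------------------------------------------------------
# type II Wald tests
# ---------------------------------------------------------------------------


def test_wald_single_df_equals_squared_z():
    fit = fit_division_logistic(_two_group_table(), "divided ~ delta_pos")
    chi2, df, p = wald_type2(fit, "delta_pos")
    z = fit.params["delta_pos"] / math.sqrt(fit.cov.loc["delta_pos", "delta_pos"])
    assert df == 1
    assert chi2 == pytest.approx(z**2, rel=1e-9)


def test_wald_matches_r_car_type2(tmp_path):
    """Independent oracle: R car::Anova type II Wald chi-squares on the same
    logistic model."""
    rng = np.random.default_rng(7)
    n = 300
    df = pd.DataFrame({
        "track_id": [str(i) for i in range(n)],
        "fish_id": rng.choice(["f1", "f2", "f3"], n),
        "treatment": "control",
        "area": rng.uniform(10, 150, n),
        "delta_pos": rng.integers(0, 2, n),
        "fate": None,
    })
    lin = -2.0 + 0.015 * df["area"] + 0.8 * df["delta_pos"]
    df["divided"] = rng.random(n) < 1 / (1 + np.exp(-lin))
    fit = fit_division_logistic(df, "divided ~ area + delta_pos + C(fish_id)")

    csv = tmp_path / "rows.csv"
    df.to_csv(csv, index=False)
    script = textwrap.dedent(f"""
        suppressMessages(library(car))
        d <- read.csv("{csv}")
        d$divided <- as.integer(d$divided == "True" | d$divided == "TRUE" | d$divided == "1")
        m <- glm(divided ~ area + delta_pos + factor(fish_id), data = d,
                 family = binomial())
        a <- Anova(m, type = 2, test.statistic = "Wald")
        write.csv(data.frame(term = rownames(a), chi2 = a[["Chisq"]]),
                  "{tmp_path / 'anova.csv'}", row.names = FALSE)
    """)
    subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
    r = pd.read_csv(tmp_path / "anova.csv").set_index("term")["chi2"]
    assert wald_type2(fit, "area")[0] == pytest.approx(r["area"], rel=1e-4)
    assert wald_type2(fit, "delta_pos")[0] == pytest.approx(r["delta_pos"], rel=1e-4)
    assert wald_type2(fit, "C(fish_id)")[0] == pytest.approx(
        r["factor(fish_id)"], rel=1e-4)


def test_wald_main_effect_refits_without_own_interaction():
    """Marginality: the type II test of a main effect equals the block Wald
    in the model with the interaction removed."""
    rng = np.random.default_rng(8)
    n = 400
    area = rng.uniform(10, 150, n)
    delta = rng.integers(0, 2, n)
    y = rng.random(n) < 1 / (1 + np.exp(-(-2 + 0.015 * area + 0.5 * delta)))
    df = pd.DataFrame({"divided": y, "area": area, "delta_pos": delta,
                       "fish_id": "f1", "treatment": "control",
                       "track_id": [str(i) for i in range(n)], "fate": None})
    full = fit_division_logistic(df, "divided ~ area * delta_pos")
    reduced = fit_division_logistic(df, "divided ~ area + delta_pos")
    chi2_full_t2, _, _ = wald_type2(full, "area")
    chi2_reduced, _, _ = wald_type2(reduced, "area")
    assert chi2_full_t2 == pytest.approx(chi2_reduced, rel=1e-9)
    # while the interaction itself is tested in the full model
    chi2_int, df_int, _ = wald_type2(full, "area:delta_pos")
    assert df_int == 1


def test_wald_null_type1_error_calibrated():
    """Under a simulated null (deltaA effect truly zero), the type II Wald
    test rejects at the nominal 5% (within 2 percentage points over 1000
    replicates)."""
    rng = np.random.default_rng(9)
    n = 200
    rejections = 0
    n_rep = 1000
    pvals = []
    for _ in range(n_rep):
        area = rng.uniform(10, 150, n)
        delta = rng.integers(0, 2, n)
        y = rng.random(n) < 1 / (1 + np.exp(-(-2.0 + 0.01 * area)))
        df = pd.DataFrame({"divided": y, "area": area, "delta_pos": delta})
        fit = fit_division_logistic(df, "divided ~ area + delta_pos")
        p = wald_type2(fit, "delta_pos")[2]
        pvals.append(p)
        rejections += p < 0.05
    assert abs(rejections / n_rep - 0.05) <= 0.02
    # p-values roughly uniform: mean near 0.5
    assert np.mean(pvals) == pytest.approx(0.5, abs=0.05)


def test_wald_detects_strong_interaction():
    rng = np.random.default_rng(10)
    n = 800
    area = rng.uniform(10, 150, n)
    delta = rng.integers(0, 2, n)
    lin = -2 + 0.005 * area + 0.04 * area * delta - 1.5 * delta
    y = rng.random(n) < 1 / (1 + np.exp(-lin))
    df = pd.DataFrame({"divided": y, "area": area, "delta_pos": delta})
    fit = fit_division_logistic(df, "divided ~ area * delta_pos")
    assert wald_type2(fit, "area:delta_pos")[2] < 0.01


# ---------------------------------------------------------------------------
# probability rescaling
# ---------------------------------------------------------------------------


def test_rescale_known_value():
    assert rescale_probability(0.5, 35.0, 4.0) == pytest.approx(0.0763, abs=5e-4)


def test_rescale_edge_cases():
    assert rescale_probability(0.0, 35.0, 4.0) == 0.0
    assert rescale_probability(0.42, 7.0, 7.0) == pytest.approx(0.42, rel=1e-12)
    with pytest.warns(UserWarning):
        assert rescale_probability(1.0, 35.0, 4.0) == 1.0


@given(
    st.floats(min_value=0.0, max_value=0.9),
    st.floats(min_value=1.0, max_value=10.0),
    st.floats(min_value=1.0, max_value=10.0),
    st.floats(min_value=1.0, max_value=10.0),
)
def test_rescale_composition_law(p, a, b, c):
    """rescale(rescale(p, a->b), b->c) == rescale(p, a->c), away from the
    floating-point saturation of intermediate probabilities at 1."""
    two_step = rescale_probability(rescale_probability(p, a, b), b, c)
    one_step = rescale_probability(p, a, c)
    assert two_step == pytest.approx(one_step, abs=1e-12)


# ---------------------------------------------------------------------------
# fate multinomial
# ---------------------------------------------------------------------------


def test_multinomial_intercept_only_equals_proportions():
    df = pd.DataFrame({
        "fate": ["neg_pos", "neg_pos", "pos_pos", "neg_neg"],
        "fish_id": "f1", "divided": True, "delta_pos": False,
    })
    fit = fit_fate_multinomial(df, "fate ~ 1")
    probs = fate_probabilities(fit).loc["f1"]
    assert probs["neg_pos"] == pytest.approx(0.5, abs=1e-6)
    assert probs["pos_pos"] == pytest.approx(0.25, abs=1e-6)
    assert probs["neg_neg"] == pytest.approx(0.25, abs=1e-6)


def test_multinomial_per_fish_saturated_identity():
    rng = np.random.default_rng(11)
    rows = []
    for fish, probs in [("f1", [0.5, 0.3, 0.2]), ("f2", [0.2, 0.2, 0.6])]:
        draws = rng.choice(["neg_pos", "pos_pos", "neg_neg"], size=60, p=probs)
        rows += [{"fate": f, "fish_id": fish, "divided": True, "delta_pos": False}
                 for f in draws]
    df = pd.DataFrame(rows)
    fit = fit_fate_multinomial(df)
    fitted = fate_probabilities(fit)
    empirical = (df.groupby("fish_id")["fate"]
                   .value_counts(normalize=True).unstack(fill_value=0.0))
    for fish in ("f1", "f2"):
        for cat in empirical.columns:
            assert fitted.loc[fish, cat] == pytest.approx(
                empirical.loc[fish, cat], abs=1e-6)


def test_multinomial_single_category_degenerate():
    df = pd.DataFrame({"fate": ["neg_pos"] * 6, "fish_id": "f1",
                       "divided": True, "delta_pos": False})
    fit = fit_fate_multinomial(df)
    assert fit.degenerate
    assert fate_probabilities(fit).loc["f1", "neg_pos"] == 1.0
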
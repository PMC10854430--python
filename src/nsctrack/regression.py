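"""Division-propensity and division-fate regressions.

Implements the study's two models: a logistic regression of whether an NSC
track divides, with apical area and deltaA expression as covariates, fish
fixed effects on the intercept, and a treatment x deltaA interaction; and a
multinomial log-linear model of the division mode of deltaA-negative
mothers.  Per-term inference uses type II Wald chi-square tests (main
effects tested in a model without their own interactions).  Probabilities
estimated over one observation window are rescaled to another assuming a
memoryless division process: 1 - p_k = (1 - p_1)^k.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .model import (
    DELTA_POS_THRESHOLD,
    LineageForest,
    ValidationError,
)
from .annotate import DivisionEvent, Mode, classify_division_mode

__all__ = [
    "RegressionRow",
    "RegressionFit",
    "SeparationError",
    "build_regression_table",
    "fit_division_logistic",
    "wald_type2",
    "rescale_probability",
    "fit_fate_multinomial",
    "predicted_division_curve",
]

DEFAULT_LOGISTIC_FORMULA = "divided ~ area * delta_pos + C(fish_id)"
DEFAULT_FATE_FORMULA = "fate ~ C(fish_id)"
CONVERGENCE_TOL = 1e-8
MAX_ITER = 200


class SeparationError(ValidationError):
    """The likelihood is unbounded (complete or quasi-complete separation)."""


@dataclass(frozen=True)
class RegressionRow:
    """One track's covariates and outcome for the propensity/fate models.

    For dividers, area and deltaA status are taken at the last pre-division
    time point; for nondividers, the average area and most prevalent status
    over the study period.
    """

    track_id: str
    fish_id: str
    treatment: str
    divided: bool
    area: float
    delta_pos: bool
    fate: Optional[Mode] = None

    def __post_init__(self):
        if self.fate is not None and not self.divided:
            raise ValidationError(
                f"track {self.track_id}: fate set on a nondividing row"
            )


@dataclass
class RegressionFit:
    """Fitted coefficients with covariance, log-likelihood and Wald tests."""

    kind: str  # "logit" | "mnlogit"
    formula: str
    params: pd.Series | pd.DataFrame
    cov: pd.DataFrame
    llf: float
    result: object = field(repr=False)
    data: pd.DataFrame = field(repr=False)
    categories: Optional[list] = None
    degenerate: bool = False

    @property
    def coefficients(self):
        return self.params

    def wald_table(self) -> pd.DataFrame:
        info = self.result.model.data.design_info
        rows = []
        for term in info.term_names:
            if term == "Intercept":
                continue
            chi2, df, p = wald_type2(self, term)
            rows.append({"term": term, "chi2": chi2, "df": df, "p": p})
        return pd.DataFrame(rows, columns=["term", "chi2", "df", "p"])

    def to_dict(self) -> dict:
        params = self.params
        if isinstance(params, pd.DataFrame):
            coeffs = {c: params[c].to_dict() for c in params.columns}
        else:
            coeffs = params.to_dict()
        return {
            "kind": self.kind,
            "formula": self.formula,
            "coefficients": coeffs,
            "loglik": self.llf,
            "degenerate": self.degenerate,
        }


def build_regression_table(
    forest: LineageForest,
    events: Sequence[DivisionEvent],
    threshold: int = DELTA_POS_THRESHOLD,
    fate_horizon: int = 1,
    from_quiescence_only: bool = True,
    roots_only: bool = True,
) -> pd.DataFrame:
    """One row per NSC track for the propensity and fate models.

    Dividers contribute their MC area and status and, when classifiable at
    ``fate_horizon`` (falling back to DC), the division mode.  Tracks with no
    area observation are excluded; the count of exclusions is stored in the
    frame's ``attrs['excluded']``.
    """
    ev_by_mother = {e.mother_track: e for e in events}
    rows = []
    excluded = 0
    for t in sorted(forest, key=lambda t: t.track_id):
        if roots_only and t.parent_id is not None:
            continue
        e = ev_by_mother.get(t.track_id)
        divided = e is not None and (e.from_quiescence or not from_quiescence_only)
        if divided:
            area = e.mother_area
            status = e.mother_status
            fate = classify_division_mode(e, forest, fate_horizon, threshold).mode
            if fate is Mode.UNCLASSIFIABLE:
                fate = classify_division_mode(e, forest, 0, threshold).mode
            fate = None if fate is Mode.UNCLASSIFIABLE else fate
        else:
            areas = t.areas()
            area = float(np.mean(areas)) if areas else None
            statuses = t.statuses(threshold)
            status = (sum(statuses) * 2 > len(statuses)) if statuses else None
            fate = None
        if area is None or status is None:
            excluded += 1
            continue
        rows.append(
            {
                "track_id": t.track_id,
                "fish_id": t.fish_id,
                "treatment": t.treatment.value,
                "divided": divided,
                "area": float(area),
                "delta_pos": bool(status),
                "fate": fate.value if fate is not None else None,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["track_id", "fish_id", "treatment", "divided", "area",
                 "delta_pos", "fate"],
    )
    table.attrs["excluded"] = excluded
    return table


def _check_separation(result, y: np.ndarray) -> None:
    p = np.asarray(result.predict())
    if y.ndim == 1:
        eps = 1e-8
        if np.all((p > 1 - eps) == (y > 0.5)) and np.all(np.abs(p - y) < eps):
            raise SeparationError(
                "complete separation: fitted probabilities are 0/1 on every row"
            )
    if not getattr(result, "mle_retvals", {}).get("converged", True):
        raise SeparationError("fit did not converge (possible separation)")


def fit_division_logistic(
    table: pd.DataFrame,
    formula: str = DEFAULT_LOGISTIC_FORMULA,
) -> RegressionFit:
    """Maximum-likelihood logistic regression of division on the design.

    The default design is ``divided ~ area * delta_pos + C(fish_id)``; add
    ``+ C(treatment):delta_pos`` for pooled control/Notch-blockade tables.
    Complete separation is detected and raised as :class:`SeparationError`
    with a diagnostic rather than silently penalized.
    """
    data = table.copy()
    data["divided"] = data["divided"].astype(int)
    data["delta_pos"] = data["delta_pos"].astype(int)
    if data["divided"].nunique() < 2:
        raise SeparationError(
            "outcome has a single class: the logistic likelihood is unbounded"
        )
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.logit(formula, data=data)
            result = model.fit(disp=0, maxiter=MAX_ITER, tol=CONVERGENCE_TOL,
                               warn_convergence=False)
    except PerfectSeparationError as exc:
        raise SeparationError(f"complete separation detected: {exc}") from exc
    _check_separation(result, data["divided"].to_numpy())
    return RegressionFit(
        kind="logit",
        formula=formula,
        params=result.params,
        cov=pd.DataFrame(result.cov_params(), index=result.params.index,
                         columns=result.params.index),
        llf=float(result.llf),
        result=result,
        data=data,
    )


def _term_factors(term_name: str) -> frozenset:
    return frozenset(f.strip() for f in term_name.split(":"))


def _reduced_formula(fit: RegressionFit, term: str) -> Optional[str]:
    """Formula without the interactions strictly containing ``term``."""
    info = fit.result.model.data.design_info
    tf = _term_factors(term)
    keep = []
    dropped = False
    for name in info.term_names:
        if name == "Intercept":
            continue
        nf = _term_factors(name)
        if nf != tf and tf < nf:
            dropped = True
            continue
        keep.append(name)
    if not dropped:
        return None
    lhs = fit.formula.split("~")[0].strip()
    return f"{lhs} ~ " + " + ".join(keep)


def wald_type2(fit: RegressionFit, term: str) -> tuple[float, float, float]:
    """Type II Wald chi-square test of one model term.

    The term's coefficient block is tested against zero using the fitted
    covariance; respecting marginality, a main effect is tested in the model
    refitted without the interactions that contain it.
    """
    info = fit.result.model.data.design_info
    if term not in info.term_names:
        raise ValidationError(f"term {term!r} not in design ({info.term_names})")
    reduced = _reduced_formula(fit, term)
    if reduced is not None:
        refit = _refit(fit, reduced)
        return _wald_block(refit, term)
    return _wald_block(fit, term)


def _refit(fit: RegressionFit, formula: str) -> RegressionFit:
    if fit.kind == "logit":
        return fit_division_logistic(fit.data, formula)
    return fit_fate_multinomial(fit.data, formula)


def _wald_block(fit: RegressionFit, term: str) -> tuple[float, float, float]:
    info = fit.result.model.data.design_info
    sl = info.term_name_slices[term]
    if fit.kind == "mnlogit":
        # stack the term's coefficients across outcome equations
        k_exog = len(info.column_names)
        n_eq = fit.result.params.shape[1]
        idx = []
        for eq in range(n_eq):
            idx.extend(range(eq * k_exog + sl.start, eq * k_exog + sl.stop))
        beta = np.asarray(fit.result.params).T.ravel()[idx]
        cov = np.asarray(fit.result.cov_params())[np.ix_(idx, idx)]
    else:
        beta = fit.result.params.iloc[sl].to_numpy()
        cov = np.asarray(fit.result.cov_params())[sl, sl]
    try:
        chi2 = float(beta @ np.linalg.solve(cov, beta))
    except np.linalg.LinAlgError as exc:
        raise ValidationError(f"singular covariance block for term {term!r}") from exc
    df = len(beta)
    p = float(sps.chi2.sf(chi2, df))
    return chi2, float(df), p


def rescale_probability(p: float, window_from: float, window_to: float) -> float:
    """Rescale a division probability between observation windows.

    Under a memoryless division process, 1 - p_k = (1 - p_1)^k, so
    ``p_to = 1 - (1 - p_from)^(window_to / window_from)``.
    """
    if not 0 <= p <= 1:
        raise ValidationError(f"p must lie in [0, 1], got {p}")
    if window_from <= 0 or window_to <= 0:
        raise ValidationError("windows must be positive")
    if p == 1:
        warnings.warn("p = 1 is degenerate under memorylessness; returning 1")
        return 1.0
    return -math.expm1((window_to / window_from) * math.log1p(-p))


def fit_fate_multinomial(
    table: pd.DataFrame,
    formula: str = DEFAULT_FATE_FORMULA,
) -> RegressionFit:
    """Multinomial log-linear model of the division mode.

    Intended for divisions of deltaA-negative mothers (rows with
    ``divided`` true and ``delta_pos`` false and a classified fate).  With
    the default intercept-plus-fish design the fitted probabilities equal
    the per-fish empirical fate proportions (the model is saturated).  A
    single observed category is degenerate and reported as such.
    """
    data = table.copy()
    data = data[data["fate"].notna()]
    if data.empty:
        raise ValidationError("no classified fates to fit")
    cats = sorted(data["fate"].unique())
    if len(cats) == 1:
        probs = pd.DataFrame({cats[0]: [1.0]})
        return RegressionFit(
            kind="mnlogit", formula=formula, params=probs, cov=pd.DataFrame(),
            llf=0.0, result=None, data=data, categories=cats, degenerate=True,
        )
    data["fate"] = pd.Categorical(data["fate"], categories=cats)
    # statsmodels needs a numeric outcome code for the multinomial formula
    data["_fate_code"] = data["fate"].cat.codes
    rhs = formula.split("~", 1)[1]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mnlogit(f"_fate_code ~ {rhs}", data=data)
            result = model.fit(disp=0, maxiter=MAX_ITER, gtol=CONVERGENCE_TOL)
    except np.linalg.LinAlgError as exc:
        raise SeparationError(
            "singular Hessian: a fate category is (quasi-)separated in the design"
        ) from exc
    names = result.model.data.design_info.column_names
    params = pd.DataFrame(
        np.asarray(result.params), index=names,
        columns=[str(c) for c in cats[1:]],
    )
    return RegressionFit(
        kind="mnlogit",
        formula=formula,
        params=params,
        cov=pd.DataFrame(np.asarray(result.cov_params())),
        llf=float(result.llf),
        result=result,
        data=data,
        categories=cats,
    )


def fate_probabilities(fit: RegressionFit) -> pd.DataFrame:
    """Fitted per-fish fate probabilities of a multinomial fit."""
    if fit.degenerate:
        return pd.DataFrame(
            {fit.categories[0]: 1.0}, index=sorted(fit.data["fish_id"].unique())
        )
    out = {}
    for fish, sub in fit.data.groupby("fish_id"):
        pred = np.asarray(fit.result.predict(sub.iloc[[0]]))[0]
        out[fish] = pred
    return pd.DataFrame(out, index=[str(c) for c in fit.categories]).T


def predicted_division_curve(
    fit: RegressionFit,
    area_grid: Sequence[float],
    delta_pos: bool,
    treatment: Optional[str] = None,
) -> pd.DataFrame:
    """P(divide | area, deltaA status) along an area grid.

    Fish fixed effects are averaged over the fish present in the fitted
    table (probabilities averaged on the response scale).
    """
    fishes = sorted(fit.data["fish_id"].unique())
    rows = []
    for a in area_grid:
        grid = pd.DataFrame(
            {
                "area": a,
                "delta_pos": int(delta_pos),
                "fish_id": fishes,
            }
        )
        if "treatment" in fit.data.columns:
            grid["treatment"] = treatment if treatment is not None \
                else fit.data["treatment"].mode()[0]
        p = float(np.mean(np.asarray(fit.result.predict(grid))))
        rows.append({"area": a, "delta_pos": delta_pos, "p_divide": p})
    return pd.DataFrame(rows)
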
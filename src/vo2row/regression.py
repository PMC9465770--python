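"""Prediction equations and their (re-)derivation by stepwise regression.

Houses the two published sex-specific equations that predict absolute
VO2max (mL·min⁻¹) from lean body mass (kg) and the distance covered in
the final 4-minute all-out stage of an incremental rowing step test (m):

    boys:  VO2max = −2310.815 + 40.991·LBM + 3.365·distance
    girls: VO2max =  −572.696 + 41.182·LBM + 1.707·distance

and re-derives equations of the same family from cohort data via
ordinary least squares with forward/backward stepwise selection on the
partial-F probability (enter 0.05 / remove 0.10, the conventional SPSS
stepwise defaults).  Coefficients are always reported in natural units;
predictors are never standardised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import Cohort

__all__ = [
    "PredictionEquation",
    "RegressionFit",
    "frozen_equation",
    "predict_vo2max",
    "predict_cohort",
    "fit_ols",
    "stepwise_ols",
    "equation_to_json",
    "equation_from_json",
]

#: canonical predictor order used by the frozen equations and tie-breaking
CANDIDATE_ORDER = (
    "lean_body_mass",
    "distance_4min",
    "mean_power",
    "hr_max",
    "stroke_rate",
)


@dataclass(frozen=True)
class PredictionEquation:
    """A linear VO2max prediction equation: intercept + Σ coefficient·value.

    ``terms`` is an ordered tuple of (predictor name, coefficient); units
    are mL·min⁻¹ for the intercept, mL·min⁻¹·kg⁻¹ for lean_body_mass and
    mL·min⁻¹·m⁻¹ for distance_4min.  ``provenance`` distinguishes the
    published coefficients ("frozen-published") from refits ("fitted").
    """

    sex: str
    intercept: float
    terms: tuple[tuple[str, float], ...]
    provenance: str = "fitted"

    def predictors(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.terms)

    def evaluate(self, values: Mapping[str, float]) -> float:
        """Exact linear evaluation; raises KeyError on a missing predictor."""
        total = self.intercept
        for name, coef in self.terms:
            if name not in values or values[name] is None:
                raise KeyError(
                    f"equation for sex={self.sex!r} requires predictor {name!r}"
                )
            total += coef * float(values[name])
        return total


_FROZEN = {
    "male": PredictionEquation(
        sex="male",
        intercept=-2310.815,
        terms=(("lean_body_mass", 40.991), ("distance_4min", 3.365)),
        provenance="frozen-published",
    ),
    "female": PredictionEquation(
        sex="female",
        intercept=-572.696,
        terms=(("lean_body_mass", 41.182), ("distance_4min", 1.707)),
        provenance="frozen-published",
    ),
}


def frozen_equation(sex: str) -> PredictionEquation:
    """The published prediction equation for one sex, coefficients verbatim."""
    try:
        return _FROZEN[sex]
    except KeyError:
        raise ValueError(f"unknown sex {sex!r}; expected 'male' or 'female'") from None


def predict_vo2max(
    eq: PredictionEquation, lean_body_mass: float, distance_4min: float, **other: float
) -> float:
    """Predicted absolute VO2max (mL·min⁻¹) for one athlete."""
    if lean_body_mass <= 0 or distance_4min <= 0:
        raise ValueError("lean_body_mass and distance_4min must be positive")
    values = {"lean_body_mass": lean_body_mass, "distance_4min": distance_4min, **other}
    return eq.evaluate(values)


def predict_cohort(eq: PredictionEquation, cohort: Cohort) -> np.ndarray:
    """Vector of predictions for every record of a cohort, in order."""
    return np.asarray(
        [eq.evaluate({n: getattr(r, n) for n in eq.predictors()}) for r in cohort],
        dtype=float,
    )


@dataclass(frozen=True)
class RegressionFit:
    """An OLS fit and its summary statistics.

    ``r_squared`` is the coefficient of determination, ``f_statistic``
    the overall model F on (df_model, df_resid) degrees of freedom,
    ``residual_sd`` the root mean squared error with the n−k−1
    denominator.  ``selected`` records the stepwise entry order;
    ``candidate_pool`` the predictors that were offered.
    """

    equation: PredictionEquation
    r: float
    r_squared: float
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    residual_sd: float
    selected: tuple[str, ...]
    candidate_pool: tuple[str, ...]
    n: int


def _design_frame(data: Cohort | pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    if isinstance(data, Cohort):
        return pd.DataFrame({c: [getattr(r, c) for r in data] for c in columns})
    return data.loc[:, list(columns)].astype(float)


def _infer_sex(data: Cohort | pd.DataFrame) -> Optional[str]:
    if isinstance(data, Cohort):
        sexes = {r.sex for r in data}
        if len(sexes) == 1:
            return sexes.pop()
    return None


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    # name predictors that are (near-)exact linear combinations of the others
    names = list(X.columns)
    bad = []
    for name in names:
        others = [c for c in names if c != name]
        if not others:
            continue
        A = sm.add_constant(X[others].to_numpy())
        y = X[name].to_numpy()
        resid = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
        denom = np.sum((y - y.mean()) ** 2)
        if denom == 0 or np.sum(resid**2) / denom < 1e-10:
            bad.append(name)
    return bad


def fit_ols(
    data: Cohort | pd.DataFrame,
    response: str = "vo2max_measured",
    predictors: Sequence[str] = ("lean_body_mass", "distance_4min"),
    sex: Optional[str] = None,
    candidate_pool: Optional[Sequence[str]] = None,
) -> RegressionFit:
    """Ordinary least-squares fit of ``response`` on ``predictors``.

    Raises on a rank-deficient design, naming the collinear columns, and
    on a constant predictor.  An empty predictor list gives the
    intercept-only fit (r² = 0).
    """
    predictors = tuple(predictors)
    frame = _design_frame(data, (response, *predictors))
    if frame.isna().any().any():
        raise ValueError("missing values in response or predictors")
    n = len(frame)
    if n <= len(predictors) + 1:
        raise ValueError(
            f"need n > k+1 observations (n={n}, k={len(predictors)})"
        )
    y = frame[response].to_numpy(dtype=float)

    if predictors:
        X = frame[list(predictors)]
        constant = [c for c in predictors if np.ptp(X[c].to_numpy()) == 0]
        if constant:
            raise ValueError(f"constant predictor(s): {constant}")
        design = sm.add_constant(X.to_numpy(), has_constant="add")
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError(
                f"rank-deficient design; collinear columns: {_collinear_columns(X)}"
            )
    else:
        design = np.ones((n, 1))

    res = sm.OLS(y, design).fit()
    coefs = res.params
    intercept = float(coefs[0])
    terms = tuple((p, float(c)) for p, c in zip(predictors, coefs[1:]))

    df_model = int(res.df_model)
    df_resid = int(res.df_resid)
    r2 = float(res.rsquared) if predictors else 0.0
    eq = PredictionEquation(
        sex=sex or _infer_sex(data) or "unspecified",
        intercept=intercept,
        terms=terms,
        provenance="fitted",
    )
    return RegressionFit(
        equation=eq,
        r=float(np.sqrt(max(r2, 0.0))),
        r_squared=r2,
        f_statistic=float(res.fvalue) if predictors else float("nan"),
        df=(df_model, df_resid),
        p_value=float(res.f_pvalue) if predictors else float("nan"),
        residual_sd=float(np.sqrt(res.ssr / df_resid)) if df_resid > 0 else 0.0,
        selected=predictors,
        candidate_pool=tuple(candidate_pool) if candidate_pool is not None else predictors,
        n=n,
    )


def _partial_p(frame: pd.DataFrame, response: str, included: Sequence[str]) -> dict[str, float]:
    """Coefficient p-values (equivalent to partial-F tests) of a fitted model."""
    X = sm.add_constant(frame[list(included)].to_numpy(), has_constant="add")
    res = sm.OLS(frame[response].to_numpy(dtype=float), X).fit()
    return {name: float(p) for name, p in zip(included, res.pvalues[1:])}


def stepwise_ols(
    data: Cohort | pd.DataFrame,
    response: str = "vo2max_measured",
    candidates: Sequence[str] = CANDIDATE_ORDER,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
    sex: Optional[str] = None,
) -> RegressionFit:
    """Forward/backward stepwise OLS on the probability of the partial F.

    Each round enters the not-yet-included candidate with the smallest
    partial-F p-value, provided it is below ``alpha_enter`` (ties broken
    by candidate order), then removes any included predictor whose
    p-value exceeds ``alpha_remove``, until the model is stable.  If no
    candidate ever passes entry the intercept-only fit is returned.  A
    revisited model terminates the loop (oscillation guard).
    """
    if alpha_enter > alpha_remove:
        raise ValueError("alpha_enter must not exceed alpha_remove")
    candidates = tuple(candidates)
    frame = _design_frame(data, (response, *candidates))
    selected: list[str] = []
    visited: set[tuple[str, ...]] = set()

    while True:
        changed = False
        # forward entry
        best_name, best_p = None, None
        for cand in candidates:
            if cand in selected:
                continue
            trial = selected + [cand]
            X = frame[trial].to_numpy()
            if np.linalg.matrix_rank(sm.add_constant(X, has_constant="add")) < len(trial) + 1:
                continue  # collinear with current model; cannot enter
            p = _partial_p(frame, response, trial)[cand]
            if p < alpha_enter and (best_p is None or p < best_p):
                best_name, best_p = cand, p
        if best_name is not None:
            selected.append(best_name)
            changed = True
        # backward removal
        while selected:
            pvals = _partial_p(frame, response, selected)
            worst = max(selected, key=lambda c: pvals[c])
            if pvals[worst] > alpha_remove:
                selected.remove(worst)
                changed = True
            else:
                break
        key = tuple(selected)
        if key in visited or not changed:
            break
        visited.add(key)

    fit = fit_ols(
        frame,
        response=response,
        predictors=tuple(selected),
        sex=sex or _infer_sex(data),
        candidate_pool=candidates,
    )
    return fit


def equation_to_json(eq: PredictionEquation, path: str | Path | None = None) -> str:
    """Serialise an equation; optionally write it to ``path``."""
    payload = {
        "sex": eq.sex,
        "intercept": eq.intercept,
        "terms": [[name, coef] for name, coef in eq.terms],
        "provenance": eq.provenance,
    }
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def equation_from_json(source: str | Path) -> PredictionEquation:
    """Load an equation from a JSON string or file path."""
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    payload = json.loads(text)
    return PredictionEquation(
        sex=payload["sex"],
        intercept=float(payload["intercept"]),
        terms=tuple((str(n), float(c)) for n, c in payload["terms"]),
        provenance=payload.get("provenance", "fitted"),
    )
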
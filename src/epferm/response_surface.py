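"""Quadratic response-surface model for the uniform-design yield data.

The fitted model is

    Y = C + b_T2*T^2 + b_T*T + b_G2*G^2 + b_G*G + sum_j a_j * F_j

with a quadratic in the sampling time T (h) and the glycerol dose G
(g/100 mL), and linear terms for the remaining five medium factors.  The
model form is fixed; no term selection is performed.  Optima follow from
the vertex -a/(2b) of each concave quadratic and from the coefficient sign
of each linear factor, clamped to the tested ranges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import DesignMatrix, to_g_per_L
from .errors import (
    CollinearityError,
    ConfigurationError,
    IncompleteDesignError,
    NoStationaryPointError,
    UnderdeterminedError,
)

__all__ = [
    "ResponseModelSpec",
    "DEFAULT_MODEL_SPEC",
    "TermStat",
    "FittedResponseModel",
    "StationaryPoint",
    "OptimumRecommendation",
    "assemble_long_table",
    "fit_quadratic_model",
    "stationary_point",
    "recommend_optimum",
    "predict_yield",
]

RESPONSE_COLUMN = "ep_ug_per_L"
TIME_COLUMN = "time_h"


@dataclass(frozen=True)
class ResponseModelSpec:
    """Which factors enter quadratically and which linearly."""

    quadratic_factors: tuple[str, ...] = (TIME_COLUMN, "glycerol")
    linear_factors: tuple[str, ...] = (
        "yeast_powder",
        "peptone",
        "znso4",
        "mgso4",
        "kh2po4",
    )
    response: str = RESPONSE_COLUMN

    def __post_init__(self):
        if set(self.quadratic_factors) & set(self.linear_factors):
            raise ValueError("quadratic and linear factor sets must be disjoint")

    @property
    def all_factors(self) -> tuple[str, ...]:
        return self.quadratic_factors + self.linear_factors

    @property
    def term_names(self) -> list[str]:
        names = []
        for f in self.quadratic_factors:
            names += [f"{f}^2", f]
        names += list(self.linear_factors)
        return names


DEFAULT_MODEL_SPEC = ResponseModelSpec()


@dataclass(frozen=True)
class TermStat:
    name: str
    coef: float
    se: float
    t: float
    p: float


@dataclass
class FittedResponseModel:
    """OLS fit of the mixed quadratic/linear yield model."""

    spec: ResponseModelSpec
    intercept: TermStat
    terms: list[TermStat]
    r_squared: float
    f_statistic: float
    f_pvalue: float
    df_model: int
    df_resid: int
    n_obs: int

    def coef(self, term: str) -> float:
        if term in ("const", "intercept"):
            return self.intercept.coef
        for t in self.terms:
            if t.name == term:
                return t.coef
        raise KeyError(term)

    def predict(self, settings: Mapping[str, float]) -> float:
        """Evaluate the fitted polynomial at one full factor setting
        (must include the sampling time)."""
        missing = [f for f in self.spec.all_factors if f not in settings]
        if missing:
            raise ConfigurationError(f"missing factor values: {missing}")
        y = self.intercept.coef
        for f in self.spec.quadratic_factors:
            v = float(settings[f])
            y += self.coef(f"{f}^2") * v * v + self.coef(f) * v
        for f in self.spec.linear_factors:
            y += self.coef(f) * float(settings[f])
        return float(y)

    def to_dict(self) -> dict:
        return {
            "model": "quadratic-response-surface",
            "response": self.spec.response,
            "intercept": vars(self.intercept),
            "terms": [vars(t) for t in self.terms],
            "r_squared": self.r_squared,
            "f_statistic": self.f_statistic,
            "f_pvalue": self.f_pvalue,
            "df": [self.df_model, self.df_resid],
            "n_obs": self.n_obs,
        }


def assemble_long_table(design: DesignMatrix) -> pd.DataFrame:
    """Unstack a design's per-time response block into one observation per
    (run, sampling time): columns run, time_h, factors..., ep_ug_per_L."""
    if design.responses is None:
        raise IncompleteDesignError("design carries no response block")
    if design.responses.isna().any().any():
        raise IncompleteDesignError("design response block has missing cells")
    if len(design.sampling_times) != design.responses.shape[1]:
        raise IncompleteDesignError(
            "response columns do not match the sampling times"
        )
    rows = []
    resp = design.responses.to_numpy(dtype=float)
    for i in range(design.n_runs):
        for j, t in enumerate(design.sampling_times):
            row = {"run": i + 1, TIME_COLUMN: float(t)}
            row.update(design.layout.iloc[i].to_dict())
            row[RESPONSE_COLUMN] = resp[i, j]
            rows.append(row)
    return pd.DataFrame(rows)


def _model_matrix(table: pd.DataFrame, spec: ResponseModelSpec):
    cols = {}
    for f in spec.quadratic_factors:
        v = table[f].to_numpy(dtype=float)
        cols[f"{f}^2"] = v * v
        cols[f] = v
    for f in spec.linear_factors:
        cols[f] = table[f].to_numpy(dtype=float)
    X = pd.DataFrame(cols)
    return sm.add_constant(X, has_constant="add")


def fit_quadratic_model(
    table: pd.DataFrame, spec: ResponseModelSpec = DEFAULT_MODEL_SPEC
) -> FittedResponseModel:
    """Ordinary least squares fit of the yield model to a long table.

    Reports classical per-term SE/t/p, the coefficient of determination and
    the overall regression F with its degrees of freedom.
    """
    missing = [c for c in (*spec.all_factors, spec.response) if c not in table]
    if missing:
        raise ConfigurationError(f"long table lacks columns: {missing}")
    X = _model_matrix(table, spec)
    y = table[spec.response].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise UnderdeterminedError(f"{n} observations cannot identify {p} parameters")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < p:
        bad = [
            c
            for c in X.columns
            if c != "const"
            and np.linalg.matrix_rank(X.drop(columns=c).to_numpy()) == rank
        ]
        raise CollinearityError(
            f"model matrix rank {rank} < {p}; redundant columns: {bad}", columns=bad
        )
    res = sm.OLS(y, X).fit()
    stats_ = {
        name: TermStat(
            name=name,
            coef=float(res.params[name]),
            se=float(res.bse[name]),
            t=float(res.tvalues[name]),
            p=float(res.pvalues[name]),
        )
        for name in X.columns
    }
    return FittedResponseModel(
        spec=spec,
        intercept=stats_["const"],
        terms=[stats_[nm] for nm in spec.term_names],
        r_squared=float(res.rsquared),
        f_statistic=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        n_obs=n,
    )


@dataclass(frozen=True)
class StationaryPoint:
    factor: str
    value: float
    kind: str  # "maximum" | "minimum"


def stationary_point(model: FittedResponseModel, factor: str) -> StationaryPoint:
    """Vertex -a/(2b) of the fitted parabola in one quadratic factor."""
    if factor not in model.spec.quadratic_factors:
        raise ConfigurationError(f"{factor!r} has no quadratic term in this model")
    a = model.coef(factor)
    b = model.coef(f"{factor}^2")
    if b == 0.0:
        raise NoStationaryPointError(f"{factor!r}: quadratic coefficient is zero")
    return StationaryPoint(
        factor=factor, value=-a / (2.0 * b), kind="maximum" if b < 0 else "minimum"
    )


@dataclass
class OptimumRecommendation:
    """Recommended factor settings with provenance per factor.

    Provenance is ``interior-stationary`` when the vertex of a concave
    quadratic lies inside the tested range, otherwise ``clamped-lower`` or
    ``clamped-upper``.  Medium settings are in g/100 mL; use
    :meth:`settings_g_per_L` for the conventional g/L formulation.
    """

    settings: dict[str, float]
    provenance: dict[str, str]
    predicted_response: float
    optimum_time_h: float

    def settings_g_per_L(self) -> dict[str, float]:
        return to_g_per_L(
            {k: v for k, v in self.settings.items() if k != TIME_COLUMN}
        )

    def to_dict(self) -> dict:
        return {
            "settings_g_per_100mL": {
                k: v for k, v in self.settings.items() if k != TIME_COLUMN
            },
            "settings_g_per_L": self.settings_g_per_L(),
            "provenance": self.provenance,
            "optimum_time_h": self.optimum_time_h,
            "predicted_response_ug_per_L": self.predicted_response,
        }


def recommend_optimum(
    model: FittedResponseModel,
    ranges: Mapping[str, tuple[float, float]],
) -> OptimumRecommendation:
    """Best factor settings under the fitted model, within the tested ranges.

    Concave quadratic factors take their interior vertex (clamped into the
    range if outside); convex ones fall back to the better range endpoint
    with a warning.  Linear factors go to the upper bound when their
    coefficient is positive, else the lower bound.
    """
    missing = [f for f in model.spec.all_factors if f not in ranges]
    if missing:
        raise ConfigurationError(f"missing tested ranges for: {missing}")

    settings: dict[str, float] = {}
    provenance: dict[str, str] = {}

    for f in model.spec.quadratic_factors:
        lo, hi = ranges[f]
        b = model.coef(f"{f}^2")
        if b < 0:
            v = stationary_point(model, f).value
            if v < lo:
                settings[f], provenance[f] = lo, "clamped-lower"
            elif v > hi:
                settings[f], provenance[f] = hi, "clamped-upper"
            else:
                settings[f], provenance[f] = v, "interior-stationary"
        else:
            warnings.warn(
                f"{f!r}: convex quadratic ({b:+.4g}); taking the better endpoint",
                stacklevel=2,
            )
            # evaluate the 1-D quadratic at both endpoints
            a = model.coef(f)
            lo_val, hi_val = b * lo * lo + a * lo, b * hi * hi + a * hi
            if hi_val >= lo_val:
                settings[f], provenance[f] = hi, "clamped-upper"
            else:
                settings[f], provenance[f] = lo, "clamped-lower"

    for f in model.spec.linear_factors:
        lo, hi = ranges[f]
        if model.coef(f) > 0:
            settings[f], provenance[f] = hi, "clamped-upper"
        else:
            settings[f], provenance[f] = lo, "clamped-lower"

    t_opt = settings.get(TIME_COLUMN, float("nan"))
    predicted = model.predict(settings)
    if predicted < 0:
        warnings.warn(
            f"predicted yield at the optimum is negative ({predicted:.3g})",
            stacklevel=2,
        )
    return OptimumRecommendation(
        settings=settings,
        provenance=provenance,
        predicted_response=predicted,
        optimum_time_h=t_opt,
    )


def predict_yield(
    model: FittedResponseModel,
    settings: Mapping[str, float],
    times: Sequence[float],
) -> np.ndarray:
    """Predicted yield at fixed medium settings over a vector of sampling
    times.  Predictions are not clipped; negative values warn."""
    out = np.empty(len(times), dtype=float)
    for i, t in enumerate(times):
        full = dict(settings)
        full[TIME_COLUMN] = float(t)
        out[i] = model.predict(full)
    if (out < 0).any():
        warnings.warn("some predicted yields are negative", stacklevel=2)
    return out
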
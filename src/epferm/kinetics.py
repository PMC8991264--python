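"""Structured batch-growth kinetics: rate laws, simulation, and
integrated-form linear fitting.

Four specific-growth-rate laws are supported, all with glycerol as the
single limiting substrate (Cs, g/L):

    monod    mu = mu_max * Cs / (ks + Cs)
    contois  mu = mu_max * Cs / (ks * X + Cs)      (viscosity inhibition)
    andrews  mu = mu_max * Cs / (ks + Cs + Cs^2/ki) (substrate inhibition)
    aibe     mu = mu_max * Cs/(ks+Cs) * kp/(kp+Cp)  (product inhibition)

Yield coupling ties biomass and product to substrate consumption:
X = X0 + Yb*(C0 - Cs), Cp = Yp*(C0 - Cs).  With that coupling each rate
law integrates in closed form to a linear relation between time and
transforms of Cs, so kinetic parameters can be recovered by ordinary
least squares of t on those transforms.  The closed forms are exact when
written with the *effective* initial substrate C0_eff = C0 + X0/Yb, which
absorbs a non-zero inoculum into the coupling.

The Contois closed form is exact because ks*X + Cs = ks*Yb*(C0_eff - Cs) + Cs.
The product-inhibition regressor set {ln[Cs/(C0-Cs)], ln(C0-Cs), ln Cs, Cs}
is exactly collinear (the log-ratio is the difference of the two single
logs), so its fit runs on the reduced basis {ln(C0-Cs), ln Cs, Cs} and the
parameters are recovered by solving the reparameterized coefficient
equations.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.integrate import solve_ivp

from .errors import (
    CollinearityError,
    InsufficientDataError,
    IntegrationFailureError,
    KineticsDomainError,
    ScheduleError,
    SingularityError,
)

__all__ = [
    "MODEL_KINDS",
    "KineticParams",
    "BatchTimeSeries",
    "FeedSchedule",
    "KineticFitResult",
    "specific_growth_rate",
    "simulate_batch",
    "simulate_fed_batch",
    "transform_regressors",
    "integrated_form_time",
    "fit_integrated",
    "compare_models",
]

logger = logging.getLogger(__name__)

MODEL_KINDS = ("monod", "contois", "andrews", "aibe")
_SUBSTRATE_FLOOR = 1e-9  # g/L

# regressor column names (shared by transform_regressors and fit_integrated)
LN_RATIO = "ln_cs_over_remaining"
LN_REMAINING = "ln_remaining"
LN_CS = "ln_cs"
CS = "cs"

_REGRESSORS = {
    "monod": [LN_RATIO, LN_REMAINING],
    "contois": [LN_CS, LN_REMAINING],
    "andrews": [LN_RATIO, LN_REMAINING, CS],
    "aibe": [LN_RATIO, LN_REMAINING, LN_CS, CS],
}
# basis actually used in the OLS fit (aibe's four columns are collinear)
_FIT_BASIS = dict(_REGRESSORS)
_FIT_BASIS["aibe"] = [LN_REMAINING, LN_CS, CS]


def _check_kind(kind: str) -> str:
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown kinetic model kind {kind!r}; expected one of {MODEL_KINDS}")
    return kind


@dataclass(frozen=True)
class KineticParams:
    """Parameters of one structured growth model.

    mu_max [1/h]; ks [g/L substrate, or g substrate per g biomass for
    contois]; ki [g/L, andrews only]; kp [product units, aibe only];
    yb [g biomass / g substrate]; yp [product units per g substrate];
    c0 [g/L initial substrate]; x0 [g/L inoculum biomass].
    """

    mu_max: float
    ks: float
    yb: float
    yp: float
    c0: float
    x0: float = 0.0
    ki: Optional[float] = None
    kp: Optional[float] = None

    def validate(self, kind: str) -> None:
        _check_kind(kind)
        for nm in ("mu_max", "ks", "yb", "yp", "c0"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be positive")
        if self.x0 < 0:
            raise ValueError("x0 must be non-negative")
        if kind == "andrews":
            if self.ki is None or self.ki <= 0:
                raise ValueError("andrews requires ki > 0")
        elif kind == "aibe":
            if self.kp is None or self.kp <= 0:
                raise ValueError("aibe requires kp > 0")

    @property
    def c0_eff(self) -> float:
        """Effective initial substrate C0 + X0/Yb (makes the integrated
        closed forms exact with a non-zero inoculum)."""
        return self.c0 + self.x0 / self.yb


@dataclass
class BatchTimeSeries:
    """Sampled fermentation trajectory.

    ``times`` in h (non-decreasing; fed-batch output repeats each event
    time with the pre- and post-event state).  Substrate/biomass in g/L;
    product in the units of Yp * (g/L substrate).
    """

    times: np.ndarray
    substrate: np.ndarray
    biomass: Optional[np.ndarray] = None
    product: Optional[np.ndarray] = None
    volume: Optional[np.ndarray] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.substrate = np.asarray(self.substrate, dtype=float)
        for nm in ("biomass", "product", "volume"):
            v = getattr(self, nm)
            if v is not None:
                setattr(self, nm, np.asarray(v, dtype=float))
        if self.times.ndim != 1 or len(self.times) != len(self.substrate):
            raise ValueError("times and substrate must be 1-D and equal length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"time_h": self.times, "substrate_g_per_L": self.substrate})
        if self.biomass is not None:
            out["biomass_g_per_L"] = self.biomass
        if self.product is not None:
            out["product"] = self.product
        if self.volume is not None:
            out["volume_L"] = self.volume
        return out


@dataclass(frozen=True)
class FeedSchedule:
    """Discrete feed events: (time h, added volume L, added substrate g)."""

    events: tuple[tuple[float, float, float], ...]
    initial_volume: float

    def __post_init__(self):
        ev = tuple((float(t), float(v), float(m)) for t, v, m in self.events)
        object.__setattr__(self, "events", ev)
        if self.initial_volume <= 0:
            raise ValueError("initial volume must be positive")
        times = [t for t, _, _ in ev]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ScheduleError("event times must be strictly increasing")
        if any(v < 0 or m < 0 for _, v, m in ev):
            raise ScheduleError("event volumes and masses must be non-negative")


# --------------------------------------------------------------------------
# rate laws

def specific_growth_rate(
    kind: str,
    params: KineticParams,
    cs,
    x=None,
    cp=None,
):
    """Specific growth rate mu [1/h]; vectorized over the state arguments."""
    _check_kind(kind)
    params.validate(kind)
    cs = np.asarray(cs, dtype=float)
    if np.any(cs < 0):
        raise KineticsDomainError("substrate concentration must be non-negative")
    if kind == "monod":
        return params.mu_max * cs / (params.ks + cs)
    if kind == "contois":
        if x is None:
            raise KineticsDomainError("contois rate requires the biomass concentration")
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise KineticsDomainError("biomass concentration must be non-negative")
        denom = params.ks * x + cs
        if np.any((denom == 0) & (cs == 0) & (x == 0)) or np.any(x == 0):
            raise SingularityError("contois rate is singular at zero biomass")
        return params.mu_max * cs / denom
    if kind == "andrews":
        return params.mu_max * cs / (params.ks + cs + cs * cs / params.ki)
    # aibe
    if cp is None:
        raise KineticsDomainError("aibe rate requires the product concentration")
    cp = np.asarray(cp, dtype=float)
    if np.any(cp < 0):
        raise KineticsDomainError("product concentration must be non-negative")
    return (
        params.mu_max * cs / (params.ks + cs) * params.kp / (params.kp + cp)
    )


def _coupled_mu(kind: str, params: KineticParams, cs: float, cp: float | None = None) -> float:
    """mu with biomass/product taken from the yield coupling (scalar)."""
    x = params.x0 + params.yb * (params.c0 - cs)
    if cp is None:
        cp = params.yp * (params.c0 - cs)
    if kind == "monod":
        return params.mu_max * cs / (params.ks + cs)
    if kind == "contois":
        return params.mu_max * cs / (params.ks * x + cs)
    if kind == "andrews":
        return params.mu_max * cs / (params.ks + cs + cs * cs / params.ki)
    return params.mu_max * cs / (params.ks + cs) * params.kp / (params.kp + cp)


# --------------------------------------------------------------------------
# simulation

def simulate_batch(
    kind: str,
    params: KineticParams,
    t_grid: Sequence[float],
    product_decay: float = 0.0,
) -> BatchTimeSeries:
    """Integrate a batch fermentation on a user time grid.

    The substrate ODE dCs/dt = -mu*X/Yb is integrated with adaptive
    Runge-Kutta (rtol 1e-8, atol 1e-10); biomass follows the coupling
    X = X0 + Yb*(C0 - Cs) exactly.  Product follows Cp = Yp*(C0 - Cs)
    when ``product_decay`` (first-order loss rate kd, 1/h) is zero, and is
    integrated alongside the substrate otherwise.
    """
    _check_kind(kind)
    params.validate(kind)
    if product_decay < 0:
        raise ValueError("product_decay must be non-negative")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or t_grid[0] != 0.0:
        raise ValueError("t_grid must be 1-D, start at 0, with >= 2 points")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")

    with_decay = product_decay > 0.0

    def rhs(t, y):
        cs = max(y[0], _SUBSTRATE_FLOOR)
        cp = y[1] if with_decay else None
        mu = _coupled_mu(kind, params, cs, cp=max(cp, 0.0) if with_decay else None)
        x = params.x0 + params.yb * (params.c0 - cs)
        dcs = -mu * x / params.yb
        if not with_decay:
            return [dcs]
        dcp = -params.yp * dcs - product_decay * y[1]
        return [dcs, dcp]

    y0 = [params.c0, 0.0] if with_decay else [params.c0]
    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        y0,
        method="RK45",
        rtol=1e-8,
        atol=1e-10,
        dense_output=True,
        t_eval=t_grid,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise IntegrationFailureError(
            f"batch integration failed for {kind}: {sol.message}"
        )
    cs = np.clip(sol.y[0], _SUBSTRATE_FLOOR, None)
    x = params.x0 + params.yb * (params.c0 - cs)
    cp = sol.y[1] if with_decay else params.yp * (params.c0 - cs)
    return BatchTimeSeries(times=t_grid, substrate=cs, biomass=x, product=cp)


def simulate_fed_batch(
    kind: str,
    params: KineticParams,
    schedule: FeedSchedule,
    t_grid: Sequence[float],
    product_decay: float = 0.0,
) -> BatchTimeSeries:
    """Batch dynamics between feed events, instantaneous mass balance at
    each event.

    At an event adding volume dV (L) carrying substrate mass m (g):
    V' = V + dV, Cs' = (Cs*V + m)/V', X' = X*V/V', Cp' = Cp*V/V'.
    Total biomass and product masses are conserved across the boundary.
    Output repeats each event time with the pre- and post-event state.
    """
    _check_kind(kind)
    params.validate(kind)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be 1-D and strictly increasing")
    t0, t_end = float(t_grid[0]), float(t_grid[-1])
    for te, _, _ in schedule.events:
        if not (t0 < te < t_end):
            raise ScheduleError(
                f"event at {te} h lies outside the simulation span ({t0}, {t_end})"
            )

    def rhs(t, y):
        cs = max(y[0], _SUBSTRATE_FLOOR)
        x, cp = max(y[1], 0.0), max(y[2], 0.0)
        if kind == "monod":
            mu = params.mu_max * cs / (params.ks + cs)
        elif kind == "contois":
            mu = params.mu_max * cs / (params.ks * x + cs) if x > 0 else 0.0
        elif kind == "andrews":
            mu = params.mu_max * cs / (params.ks + cs + cs * cs / params.ki)
        else:
            mu = params.mu_max * cs / (params.ks + cs) * params.kp / (params.kp + cp)
        dcs = -mu * x / params.yb
        return [dcs, mu * x, -params.yp * dcs - product_decay * cp]

    times_out, cs_out, x_out, cp_out, v_out = [], [], [], [], []
    state = np.array([params.c0, params.x0, 0.0])
    vol = schedule.initial_volume
    seg_start = t0
    first_segment = True
    for te, dv, m in list(schedule.events) + [(t_end, None, None)]:
        mask = (t_grid >= seg_start) & (t_grid <= te)
        eval_pts = np.unique(np.concatenate([[seg_start], t_grid[mask], [te]]))
        sol = solve_ivp(
            rhs, (seg_start, te), state, method="RK45",
            rtol=1e-8, atol=1e-10, t_eval=eval_pts,
        )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise IntegrationFailureError(
                f"fed-batch integration failed for {kind}: {sol.message}"
            )
        # the segment start duplicates the already-emitted post-event state
        lo = 0 if first_segment else 1
        first_segment = False
        times_out.extend(sol.t[lo:])
        cs_out.extend(np.clip(sol.y[0][lo:], _SUBSTRATE_FLOOR, None))
        x_out.extend(sol.y[1][lo:])
        cp_out.extend(sol.y[2][lo:])
        v_out.extend([vol] * (len(sol.t) - lo))
        state = sol.y[:, -1].copy()
        if dv is not None:
            new_vol = vol + dv
            state = np.array(
                [
                    (max(state[0], 0.0) * vol + m) / new_vol,
                    state[1] * vol / new_vol,
                    state[2] * vol / new_vol,
                ]
            )
            vol = new_vol
            times_out.append(te)
            cs_out.append(state[0])
            x_out.append(state[1])
            cp_out.append(state[2])
            v_out.append(vol)
        seg_start = te
    return BatchTimeSeries(
        times=np.array(times_out),
        substrate=np.array(cs_out),
        biomass=np.array(x_out),
        product=np.array(cp_out),
        volume=np.array(v_out),
    )


# --------------------------------------------------------------------------
# integrated (linearized) forms

def _transform_columns(cs: np.ndarray, c0_eff: float) -> dict[str, np.ndarray]:
    rem = c0_eff - cs
    return {
        LN_RATIO: np.log(cs / rem),
        LN_REMAINING: np.log(rem),
        LN_CS: np.log(cs),
        CS: cs,
    }


def integrated_form_time(
    kind: str, params: KineticParams, cs, c_constant: float = 0.0
) -> np.ndarray:
    """Closed-form time at substrate level(s) ``cs`` under yield coupling.

    This is the analytic solution of the batch ODE written as
    t = sum(coef * transform(Cs)) + C_constant with C0_eff = C0 + X0/Yb;
    it serves as the independent oracle for the numerical simulator and as
    the data-generating identity behind the linearized fits.
    """
    _check_kind(kind)
    params.validate(kind)
    cs = np.asarray(cs, dtype=float)
    c0 = params.c0_eff
    mu = params.mu_max
    cols = _transform_columns(cs, c0)
    if kind == "monod":
        t = -params.ks / (c0 * mu) * cols[LN_RATIO] + cols[LN_REMAINING] / mu
    elif kind == "contois":
        t = -params.ks * params.yb / mu * cols[LN_CS] + cols[LN_REMAINING] / mu
    elif kind == "andrews":
        t = (
            -params.ks / (c0 * mu) * cols[LN_RATIO]
            + (1.0 + c0 / params.ki) / mu * cols[LN_REMAINING]
            + cols[CS] / (params.ki * mu)
        )
    else:  # aibe
        # With an inoculum the product couples to the true C0 while biomass
        # couples to C0_eff, so the inhibition denominator becomes
        # kp + Cp = kp_eff + Yp*(C0_eff - Cs) with
        # kp_eff = kp - Yp*X0/Yb; the two log terms scale by q = kp_eff/kp.
        r = params.yp / params.kp
        q = 1.0 - r * params.x0 / params.yb
        t = (
            -q * params.ks / (c0 * mu) * cols[LN_RATIO]
            + q * cols[LN_REMAINING] / mu
            - params.ks * r / mu * cols[LN_CS]
            - r / mu * cols[CS]
        )
    return t + c_constant


def transform_regressors(
    kind: str,
    series: BatchTimeSeries,
    c0_eff: float,
    min_consumed: float = 0.0,
) -> tuple[pd.DataFrame, int]:
    """Build the linearized-fit table: response ``time_h`` plus the
    model's transformed substrate regressors.

    Points at Cs >= C0_eff (the t = 0 sample) fall outside the log domain
    and are dropped; the count is returned and logged.  Substrate above
    C0_eff beyond rounding tolerance is a domain error (suggesting a larger
    effective initial substrate).

    ``min_consumed`` (g/L) extends the exclusion to noisy data: the
    ln(C0_eff - Cs) transform amplifies relative measurement noise by
    Cs/(C0_eff - Cs), so samples whose consumed substrate is within a few
    noise SDs of zero carry no kinetic information and destabilize the
    fit.  Points with C0_eff - Cs < min_consumed are dropped (and counted)
    before fitting; the default 0 keeps only the exact-singularity rule.
    """
    _check_kind(kind)
    if c0_eff <= 0:
        raise ValueError("c0_eff must be positive")
    if min_consumed < 0:
        raise ValueError("min_consumed must be non-negative")
    cs = np.asarray(series.substrate, dtype=float)
    t = np.asarray(series.times, dtype=float)
    if np.any(cs <= 0):
        raise KineticsDomainError("substrate values must be positive")
    if min_consumed == 0.0 and np.any(cs > c0_eff * (1.0 + 1e-9)):
        raise KineticsDomainError(
            f"substrate exceeds C0_eff = {c0_eff}; supply a larger effective "
            "initial substrate (C0 + X0/Yb) or set min_consumed"
        )
    keep = cs < c0_eff * (1.0 - 1e-12)
    if min_consumed > 0.0:
        keep &= (c0_eff - cs) >= min_consumed
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "transform_regressors(%s): dropped %d point(s) at Cs = C0_eff",
            kind,
            n_dropped,
        )
    names = _REGRESSORS[kind]
    if keep.sum() < len(names) + 2:
        raise InsufficientDataError(
            f"{kind}: {int(keep.sum())} usable points < minimum {len(names) + 2}"
        )
    cols = _transform_columns(cs[keep], c0_eff)
    table = pd.DataFrame({"time_h": t[keep], **{nm: cols[nm] for nm in names}})
    return table, n_dropped


@dataclass
class KineticFitResult:
    """One integrated-form fit: regression statistics plus the kinetic
    parameters recovered from the coefficients."""

    kind: str
    intercept: float
    intercept_se: float
    intercept_t: float
    intercept_p: float
    coefficients: pd.DataFrame  # index: regressor, cols: coef/se/t/p
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    f_pvalue: float
    df_model: int
    df_resid: int
    n_obs: int
    n_dropped: int
    cond_number: float
    params_recovered: dict[str, float]
    warnings: list[str] = field(default_factory=list)
    failed: bool = False
    error: Optional[str] = None

    @property
    def n_parameters(self) -> int:
        return len(self.coefficients) + 1

    def to_dict(self) -> dict:
        return {
            "model": self.kind,
            "intercept": {
                "coef": self.intercept,
                "se": self.intercept_se,
                "t": self.intercept_t,
                "p": self.intercept_p,
            },
            "coefficients": {
                nm: {k: float(v) for k, v in row.items()}
                for nm, row in self.coefficients.iterrows()
            },
            "r_squared": self.r_squared,
            "adj_r_squared": self.adj_r_squared,
            "f_statistic": self.f_statistic,
            "f_pvalue": self.f_pvalue,
            "df": [self.df_model, self.df_resid],
            "n_obs": self.n_obs,
            "n_dropped": self.n_dropped,
            "cond_number": self.cond_number,
            "params_recovered": self.params_recovered,
            "warnings": list(self.warnings),
            "failed": self.failed,
            "error": self.error,
        }


def _recover_parameters(
    kind: str, b: Mapping[str, float], c0_eff: float,
    yb: Optional[float], yp: Optional[float], delta: float = 0.0,
) -> tuple[dict[str, float], list[str]]:
    notes: list[str] = []
    out: dict[str, float] = {}
    if kind == "monod":
        mu = 1.0 / b[LN_REMAINING]
        out["mu_max"] = mu
        out["ks"] = -b[LN_RATIO] * c0_eff * mu
    elif kind == "contois":
        mu = 1.0 / b[LN_REMAINING]
        out["mu_max"] = mu
        if yb is not None:
            out["ks"] = -b[LN_CS] * mu / yb
        else:
            out["ks_times_yb"] = -b[LN_CS] * mu
            notes.append("contois ks requires the biomass yield Yb; reported ks*Yb")
    elif kind == "andrews":
        inv_mu = b[LN_REMAINING] - c0_eff * b[CS]
        mu = 1.0 / inv_mu
        out["mu_max"] = mu
        out["ki"] = 1.0 / (b[CS] * mu)
        out["ks"] = -b[LN_RATIO] * c0_eff * mu
    else:  # aibe, reduced basis {ln_remaining, ln_cs, cs}
        c_m, c_l, c_c = b[LN_REMAINING], b[LN_CS], b[CS]
        # With q = kp_eff/kp = 1 + c_c*delta*mu (delta = X0/Yb) and
        # r = Yp/kp:
        #   c_m = q*(1 + ks/C0)/mu
        #   c_l = -q*ks/(C0*mu) - ks*r/mu
        #   c_c = -r/mu
        # Eliminating ks and r leaves a quadratic in mu:
        #   (c_l*c_c*delta + A*B) mu^2 + (c_l + A - B) mu - 1 = 0,
        #   A = c_m - c_c*delta, B = c_c*(delta - C0).
        # Among real roots exactly one is physically admissible
        # (mu, ks, r, q all positive) away from degenerate cases.
        A = c_m - c_c * delta
        B = c_c * (delta - c0_eff)
        a_q = c_l * c_c * delta + A * B
        b_q = c_l + A - B
        roots = np.roots([a_q, b_q, -1.0]) if a_q != 0 else np.array([1.0 / b_q])
        roots = np.sort(roots[np.isreal(roots)].real)
        cand = []
        for mu in roots:
            if mu <= 0:
                continue
            q = 1.0 + c_c * delta * mu
            r = -c_c * mu
            if q <= 0:
                continue
            ks = c0_eff * (c_m * mu / q - 1.0)
            if ks > 0 and r > 0:
                cand.append((mu, ks, r))
        if not cand:
            notes.append("aibe recovery found no admissible root")
            mu = ks = r = float("nan")
        else:
            if len(cand) > 1:
                notes.append("aibe recovery ambiguous; reporting the slower-growth root")
            mu, ks, r = cand[0]
        out["mu_max"], out["ks"], out["yp_over_kp"] = mu, ks, r
        if yp is not None and r > 0:
            out["kp"] = yp / r
    if out.get("mu_max", 1.0) <= 0 or not np.isfinite(out.get("mu_max", 1.0)):
        notes.append("recovered mu_max is not positive; fit is implausible")
    if out.get("ks", 1.0) <= 0:
        notes.append("recovered ks is not positive; fit is implausible")
    return out, notes


def fit_integrated(
    kind: str,
    series: BatchTimeSeries,
    c0_eff: float,
    yb: Optional[float] = None,
    yp: Optional[float] = None,
    x0: float = 0.0,
    min_consumed: float = 0.0,
) -> KineticFitResult:
    """OLS fit of time on the integrated-form regressors, with kinetic
    parameters recovered from the coefficients.

    ``yb`` is needed to split ks out of the Contois slope; ``yp`` to split
    kp out of the product-inhibition ratio Yp/kp.  A known inoculum ``x0``
    (with ``yb``) corrects the product-inhibition recovery for the offset
    between the substrate the biomass coupling sees (C0_eff) and the
    substrate the product coupling sees (C0); with x0 = 0 the recovered
    product-inhibition parameters are effective values.  The condition
    number of the regressor matrix is reported; > 1e6 warns, > 1e10 is an
    error.
    """
    if x0 < 0:
        raise ValueError("x0 must be non-negative")
    delta = 0.0
    if x0 > 0:
        if yb is None:
            raise ValueError("a non-zero x0 requires the biomass yield yb")
        delta = x0 / yb
    table, n_dropped = transform_regressors(
        kind, series, c0_eff, min_consumed=min_consumed
    )
    basis = _FIT_BASIS[kind]
    X = sm.add_constant(table[basis], has_constant="add")
    cond = float(np.linalg.cond(X.to_numpy()))
    if cond > 1e10:
        raise CollinearityError(
            f"{kind}: regressor matrix condition number {cond:.3g} > 1e10",
            columns=basis,
        )
    notes: list[str] = []
    if cond > 1e6:
        notes.append(f"ill-conditioned regressors (cond = {cond:.3g})")
    res = sm.OLS(table["time_h"].to_numpy(), X).fit()
    coefs = pd.DataFrame(
        {
            "coef": res.params[basis],
            "se": res.bse[basis],
            "t": res.tvalues[basis],
            "p": res.pvalues[basis],
        }
    )
    recovered, rec_notes = _recover_parameters(
        kind, res.params.to_dict(), c0_eff, yb, yp, delta=delta
    )
    notes.extend(rec_notes)
    return KineticFitResult(
        kind=kind,
        intercept=float(res.params["const"]),
        intercept_se=float(res.bse["const"]),
        intercept_t=float(res.tvalues["const"]),
        intercept_p=float(res.pvalues["const"]),
        coefficients=coefs,
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        f_statistic=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        n_obs=int(res.nobs),
        n_dropped=n_dropped,
        cond_number=cond,
        params_recovered=recovered,
        warnings=notes,
    )


def compare_models(
    series: BatchTimeSeries,
    c0_eff: float,
    yb: Optional[float] = None,
    yp: Optional[float] = None,
    x0: float = 0.0,
    min_consumed: float = 0.0,
) -> list[KineticFitResult]:
    """Fit all four structured models and rank them.

    Ranking: adjusted R^2 (desc), ties by overall F (desc), then by fewer
    parameters.  A model whose fit raises is kept in the output flagged as
    failed and ranked last.  Deterministic for a fixed input.
    """
    results: list[KineticFitResult] = []
    for kind in MODEL_KINDS:
        try:
            results.append(
                fit_integrated(
                    kind, series, c0_eff, yb=yb, yp=yp, x0=x0,
                    min_consumed=min_consumed,
                )
            )
        except Exception as exc:  # noqa: BLE001 - per-model failure is data
            results.append(
                KineticFitResult(
                    kind=kind,
                    intercept=float("nan"),
                    intercept_se=float("nan"),
                    intercept_t=float("nan"),
                    intercept_p=float("nan"),
                    coefficients=pd.DataFrame(
                        columns=["coef", "se", "t", "p"], dtype=float
                    ),
                    r_squared=float("nan"),
                    adj_r_squared=float("nan"),
                    f_statistic=float("nan"),
                    f_pvalue=float("nan"),
                    df_model=0,
                    df_resid=0,
                    n_obs=0,
                    n_dropped=0,
                    cond_number=float("nan"),
                    params_recovered={},
                    failed=True,
                    error=f"{type(exc).__name__}: {exc}",
                )
            )

    def key(r: KineticFitResult):
        if r.failed:
            return (1, 0.0, 0.0, 99, MODEL_KINDS.index(r.kind))
        return (
            0,
            -r.adj_r_squared,
            -r.f_statistic,
            r.n_parameters,
            MODEL_KINDS.index(r.kind),
        )

    return sorted(results, key=key)
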
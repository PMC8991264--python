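"""Seeded synthetic data with the statistical structure the fits assume.

Two generators:

* design responses — the quadratic response-surface polynomial evaluated
  on a design's (run, time) grid plus additive Gaussian noise (the OLS
  error model);
* batch trajectories — noiseless yield-coupled simulation from one of the
  four structured growth models, then independent multiplicative
  log-normal noise per measured channel (concentrations are positive, so
  a multiplicative error model is the minimal faithful choice).

Defaults are calibrated to the reference fermentation run this package
models: glycerol falling from 34.34 g/L to ~21 g/L over 80 h and product
on the scale of a few hundred ug/L.  An optional first-order product-decay
rate ``kd`` extends the generator beyond the yield-coupled model (which
cannot produce a post-peak product decline); the default is kd = 0 so the
core generator matches the model exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .design import DesignMatrix
from .kinetics import (
    BatchTimeSeries,
    FeedSchedule,
    KineticParams,
    simulate_batch,
)

__all__ = [
    "DesignNoiseSpec",
    "TrajectoryNoiseSpec",
    "generate_design_responses",
    "generate_batch_series",
    "make_group_fixtures",
    "default_trajectory_spec",
    "default_batch_params",
    "GROUP_KINETICS",
]

# Product-inhibition kinetics used for the three fed-batch verification
# groups: dilution relieves the product term, so water addition (group 2)
# and glycerol feeding (group 3) both raise the final product mass.
GROUP_KINETICS = (
    "aibe",
    KineticParams(mu_max=0.1, ks=5.0, yb=0.5, yp=19.6, c0=34.34, x0=0.5, kp=150.0),
)


def _load_default_config() -> dict:
    ref = resources.files("epferm.data").joinpath("default_batch.yaml")
    return yaml.safe_load(ref.read_text())


def default_batch_params() -> tuple[str, KineticParams]:
    """Calibrated (kind, params) for the reference batch run."""
    cfg = _load_default_config()
    return cfg["kind"], KineticParams(**cfg["params"])


@dataclass(frozen=True)
class DesignNoiseSpec:
    """Truth + noise for synthetic design-response tables.

    ``coefficients`` is the 10-vector (intercept, T^2, T, G^2, G, F3..F7)
    of the response polynomial; ``sd`` the additive Gaussian noise SD in
    the response units (ug/L).
    """

    coefficients: tuple[float, ...]
    sd: float
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "coefficients", tuple(float(c) for c in self.coefficients)
        )
        if len(self.coefficients) != 10:
            raise ValueError("coefficient vector must have length 10")
        if self.sd < 0:
            raise ValueError("noise SD must be non-negative")


@dataclass(frozen=True)
class TrajectoryNoiseSpec:
    """Kinetic truth + sampling + multiplicative noise for one trajectory."""

    kind: str
    params: KineticParams
    times: tuple[float, ...]
    cv_substrate: float = 0.0
    cv_biomass: float = 0.0
    cv_product: float = 0.0
    product_decay: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        self.params.validate(self.kind)
        for nm in ("cv_substrate", "cv_biomass", "cv_product", "product_decay"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be non-negative")
        if self.times[0] != 0.0 or any(
            b <= a for a, b in zip(self.times, self.times[1:])
        ):
            raise ValueError("times must start at 0 and be strictly increasing")


def default_trajectory_spec(
    seed: int = 0, noisy: bool = True, product_decay: Optional[float] = None
) -> TrajectoryNoiseSpec:
    """The calibrated default trajectory spec (see data/default_batch.yaml)."""
    cfg = _load_default_config()
    kind = cfg["kind"]
    params = KineticParams(**cfg["params"])
    t_end, n = cfg["sampling"]["t_end"], cfg["sampling"]["n_points"]
    times = tuple(np.linspace(0.0, t_end, n))
    noise = cfg["noise"] if noisy else {"cv_substrate": 0, "cv_biomass": 0, "cv_product": 0}
    return TrajectoryNoiseSpec(
        kind=kind,
        params=params,
        times=times,
        cv_substrate=noise["cv_substrate"],
        cv_biomass=noise["cv_biomass"],
        cv_product=noise["cv_product"],
        product_decay=(
            cfg["product_decay"] if product_decay is None else product_decay
        ),
        seed=seed,
    )


def _polynomial(coefs: Sequence[float], t: float, g: float, f3_f7: Sequence[float]) -> float:
    c, bt2, bt, bg2, bg, *lin = coefs
    return (
        c
        + bt2 * t * t
        + bt * t
        + bg2 * g * g
        + bg * g
        + float(np.dot(lin, f3_f7))
    )


def generate_design_responses(
    design: DesignMatrix, spec: DesignNoiseSpec
) -> DesignMatrix:
    """Attach synthetic responses (polynomial + Gaussian noise) to a design.

    Responses may be negative — no clipping — so the OLS error model holds
    exactly.  Returns a new DesignMatrix; validation of response
    non-negativity is intentionally bypassed for the synthetic block.
    """
    if not design.sampling_times:
        raise ValueError("design must define sampling times")
    rng = np.random.default_rng(spec.seed)
    layout = design.layout
    glycerol = layout["glycerol"].to_numpy(dtype=float)
    others = layout.drop(columns="glycerol").to_numpy(dtype=float)
    values = np.empty((design.n_runs, len(design.sampling_times)))
    for i in range(design.n_runs):
        for j, t in enumerate(design.sampling_times):
            values[i, j] = _polynomial(spec.coefficients, float(t), glycerol[i], others[i])
    values = values + rng.normal(0.0, spec.sd, size=values.shape)
    responses = pd.DataFrame(
        values, columns=[f"ep_{int(t)}h" for t in design.sampling_times]
    )
    return DesignMatrix(
        factors=list(design.factors),
        layout=design.layout.copy(),
        sampling_times=tuple(design.sampling_times),
        responses=responses,
        allow_negative_responses=True,
    )


def generate_batch_series(spec: TrajectoryNoiseSpec) -> BatchTimeSeries:
    """Simulate a batch trajectory and apply per-channel multiplicative
    log-normal noise (mean-one; sigma chosen so the coefficient of
    variation equals the requested CV)."""
    clean = simulate_batch(
        spec.kind, spec.params, np.asarray(spec.times), product_decay=spec.product_decay
    )
    rng = np.random.default_rng(spec.seed)

    def jitter(values: np.ndarray, cv: float) -> np.ndarray:
        if cv == 0.0:
            return values.copy()
        sigma = float(np.sqrt(np.log1p(cv * cv)))
        factors = rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=len(values))
        return values * factors

    return BatchTimeSeries(
        times=clean.times.copy(),
        substrate=jitter(clean.substrate, spec.cv_substrate),
        biomass=jitter(clean.biomass, spec.cv_biomass),
        product=jitter(clean.product, spec.cv_product),
    )


def make_group_fixtures(
    seed: int = 0,
) -> tuple[list[FeedSchedule], TrajectoryNoiseSpec]:
    """The three fed-batch verification groups in a 15-L working volume.

    Group 1: no additions.  Group 2: 1 L water at 40 h and 60 h.
    Group 3: 1 L of 30% w/v glycerol (300 g) at 40 h and 60 h — 600 g fed
    on top of the initial charge.
    """
    schedules = [
        FeedSchedule(events=(), initial_volume=15.0),
        FeedSchedule(events=((40.0, 1.0, 0.0), (60.0, 1.0, 0.0)), initial_volume=15.0),
        FeedSchedule(
            events=((40.0, 1.0, 300.0), (60.0, 1.0, 300.0)), initial_volume=15.0
        ),
    ]
    kind, params = GROUP_KINETICS
    spec = TrajectoryNoiseSpec(
        kind=kind,
        params=params,
        times=tuple(np.linspace(0.0, 80.0, 21)),
        cv_substrate=0.02,
        cv_biomass=0.02,
        cv_product=0.02,
        seed=seed,
    )
    return schedules, spec
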
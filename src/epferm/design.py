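"""U-type uniform designs, the packaged 10-run medium-screening table, and
many-to-one group comparisons.

A uniform design U_n(n^s) spreads n runs over s factors, each tested at n
levels, so that every factor column uses each level exactly once and the
design points fill the factor space as evenly as possible.  Evenness is
scored by the centered L2-discrepancy of the points mapped into the unit
cube; candidate columns come from the good-lattice-point construction and
the returned design is the column subset with the smallest discrepancy.

The packaged fixture is a 10-run, 6-factor design over a fungal fermentation
medium (glycerol, yeast powder, peptone, ZnSO4, MgSO4, KH2PO4; all in
g/100 mL) with ergosterol-peroxide responses (ug/L) measured at 28, 56, 84
and 112 h.
"""

from __future__ import annotations

import hashlib
import itertools
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    CapacityError,
    DegenerateVarianceError,
    FixtureIntegrityError,
    InsufficientGroupsError,
    InvalidGeneratorError,
)

__all__ = [
    "FactorDefinition",
    "DesignMatrix",
    "MonoFactorDataset",
    "DunnettResult",
    "construct_uniform_design",
    "centered_l2_discrepancy",
    "load_design_fixture",
    "one_way_anova_dunnett",
    "to_g_per_L",
    "FIXTURE_SHA256",
]

FIXTURE_SHA256 = "1dd0f2827c8ebc91454ddcd40cfbe7ac91422fa9a18ded2120b40ecc7b92406f"
_FIXTURE_NAME = "u10_design.csv"
FIXTURE_SAMPLING_TIMES = (28.0, 56.0, 84.0, 112.0)


@dataclass(frozen=True)
class FactorDefinition:
    """One design factor and its tested levels.

    ``levels`` must be strictly increasing and positive; medium components
    are dosed in g per 100 mL, the sampling-time control variable in h.
    """

    name: str
    units: str
    levels: tuple[float, ...]
    role: str = "medium-component"

    def __post_init__(self):
        levels = tuple(float(v) for v in self.levels)
        object.__setattr__(self, "levels", levels)
        if self.role not in ("medium-component", "control-variable"):
            raise ValueError(f"unknown factor role {self.role!r}")
        if any(v <= 0 for v in levels):
            raise ValueError(f"factor {self.name!r}: levels must be positive")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError(f"factor {self.name!r}: levels must be strictly increasing")

    @property
    def range(self) -> tuple[float, float]:
        return (self.levels[0], self.levels[-1])


@dataclass
class DesignMatrix:
    """A balanced U-type design, optionally with its measured responses.

    ``layout`` holds concrete level values (one column per factor, one row
    per run); ``responses`` — when present — holds one column per sampling
    time (``ep_28h`` etc., ug/L).
    """

    factors: list[FactorDefinition]
    layout: pd.DataFrame
    sampling_times: tuple[float, ...] = ()
    responses: Optional[pd.DataFrame] = None
    #: synthetic (unclipped) response blocks may go negative
    allow_negative_responses: bool = False

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        names = [f.name for f in self.factors]
        if list(self.layout.columns) != names:
            raise ValueError("layout columns do not match factor definitions")
        for f in self.factors:
            col = np.sort(self.layout[f.name].to_numpy(dtype=float))
            if not np.allclose(col, np.asarray(f.levels)):
                raise ValueError(
                    f"column {f.name!r} is not a permutation of its levels "
                    "(U-design balance violated)"
                )
        if self.responses is not None:
            if len(self.responses) != len(self.layout):
                raise ValueError("responses row count differs from layout")
            if (
                not self.allow_negative_responses
                and (self.responses.to_numpy(dtype=float) < 0).any()
            ):
                raise ValueError("negative response concentrations")

    @property
    def n_runs(self) -> int:
        return len(self.layout)

    def to_frame(self) -> pd.DataFrame:
        """Design plus responses as one flat table (CSV schema)."""
        out = self.layout.copy()
        out.insert(0, "run", np.arange(1, self.n_runs + 1))
        if self.responses is not None:
            for c in self.responses.columns:
                out[c] = self.responses[c].to_numpy()
        return out


def to_g_per_L(values_g_per_100mL):
    """Convert medium dosages from g/100 mL (fixture units) to g/L."""
    if isinstance(values_g_per_100mL, dict):
        return {k: 10.0 * v for k, v in values_g_per_100mL.items()}
    return 10.0 * np.asarray(values_g_per_100mL, dtype=float)


# --------------------------------------------------------------------------
# construction

def _coprimes(m: int) -> list[int]:
    return [h for h in range(1, m) if math.gcd(h, m) == 1]


def centered_l2_discrepancy(points: np.ndarray) -> float:
    """Centered L2-discrepancy of points in the unit cube (Hickernell).

    Lower is more uniform.  ``points`` is (n, s).
    """
    x = np.asarray(points, dtype=float)
    if x.ndim != 2:
        raise ValueError("points must be a 2-D array")
    n, s = x.shape
    d = np.abs(x - 0.5)
    prod1 = np.prod(1.0 + 0.5 * d - 0.5 * d * d, axis=1)
    # pairwise kernel
    di = d[:, None, :]
    dj = d[None, :, :]
    dij = np.abs(x[:, None, :] - x[None, :, :])
    prod2 = np.prod(1.0 + 0.5 * di + 0.5 * dj - 0.5 * dij, axis=2)
    cd2 = (13.0 / 12.0) ** s - (2.0 / n) * prod1.sum() + prod2.sum() / n**2
    return float(np.sqrt(cd2))


def _glp_candidate_columns(n_runs: int, n_factors: int):
    """Good-lattice-point candidate columns (level indices 1..n per run).

    Uses generators coprime with n when Euler's totient allows, otherwise
    the standard plus-one trick: build the lattice modulo n+1 and drop the
    last (all-level-n+1) row, which preserves balance.
    """
    n = n_runs
    if len(_coprimes(n)) >= n_factors:
        modulus = n
    else:
        modulus = n + 1
    gens = _coprimes(modulus)
    i = np.arange(1, n + 1)
    cols = {}
    for h in gens:
        u = (i * h) % modulus
        if modulus == n:
            u = np.where(u == 0, n, u)
        cols[h] = u
    return modulus, cols


def construct_uniform_design(
    n_runs: int,
    factor_defs: Sequence[FactorDefinition],
    generator_set: Optional[Sequence[int]] = None,
) -> DesignMatrix:
    """Build a balanced U-type design by the good-lattice-point method.

    Each factor must carry exactly ``n_runs`` levels.  When
    ``generator_set`` is omitted, all coprime lattice generators are
    enumerated and the column subset with the smallest centered
    L2-discrepancy is selected exhaustively (feasible for the small run
    counts uniform designs are used at).
    """
    factor_defs = list(factor_defs)
    s = len(factor_defs)
    if s == 0:
        raise CapacityError("at least one factor is required")
    if s > n_runs - 1:
        raise CapacityError(
            f"{s} factors exceed the capacity of a {n_runs}-run U-type design "
            f"(at most {n_runs - 1})"
        )
    for f in factor_defs:
        if len(f.levels) != n_runs:
            raise ValueError(
                f"factor {f.name!r} has {len(f.levels)} levels; "
                f"a {n_runs}-run design needs exactly {n_runs}"
            )

    modulus, cols = _glp_candidate_columns(n_runs, s)

    if generator_set is not None:
        generator_set = [int(h) for h in generator_set]
        if len(generator_set) != s:
            raise InvalidGeneratorError(
                f"need {s} generators, got {len(generator_set)}"
            )
        bad = [h for h in generator_set if math.gcd(h % modulus, modulus) != 1 or h % modulus == 0]
        if bad:
            raise InvalidGeneratorError(
                f"generators {bad} are not coprime with the modulus {modulus}"
            )
        chosen = tuple(h % modulus for h in generator_set)
    else:
        if s > len(cols):
            raise CapacityError(
                f"only {len(cols)} good-lattice columns exist for {n_runs} runs"
            )
        n_subsets = math.comb(len(cols), s)
        if n_subsets > 500_000:
            raise CapacityError(
                f"exhaustive column search over {n_subsets} subsets is not supported"
            )
        best, best_cd = None, np.inf
        for subset in itertools.combinations(sorted(cols), s):
            u = np.column_stack([cols[h] for h in subset])
            pts = (u - 0.5) / n_runs
            cd = centered_l2_discrepancy(pts)
            if cd < best_cd - 1e-15:
                best, best_cd = subset, cd
        chosen = best

    data = {}
    for f, h in zip(factor_defs, chosen):
        idx = cols[h] - 1
        data[f.name] = np.asarray(f.levels)[idx]
    layout = pd.DataFrame(data)
    return DesignMatrix(factors=factor_defs, layout=layout)


# --------------------------------------------------------------------------
# packaged fixture

def load_design_fixture() -> DesignMatrix:
    """Load the packaged 10-run, 6-factor medium design with its measured
    ergosterol-peroxide responses at 28/56/84/112 h.

    The file checksum and the U-design balance are validated; any
    corruption raises :class:`FixtureIntegrityError`.
    """
    ref = resources.files("epferm.data").joinpath(_FIXTURE_NAME)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != FIXTURE_SHA256:
        raise FixtureIntegrityError(
            f"design fixture checksum mismatch ({digest[:12]}...)"
        )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw))
    factor_names = ["glycerol", "yeast_powder", "peptone", "znso4", "mgso4", "kh2po4"]
    resp_names = ["ep_28h", "ep_56h", "ep_84h", "ep_112h"]
    try:
        factors = [
            FactorDefinition(
                name=name,
                units="g/100 mL",
                levels=tuple(sorted(df[name].astype(float))),
            )
            for name in factor_names
        ]
        design = DesignMatrix(
            factors=factors,
            layout=df[factor_names].astype(float),
            sampling_times=FIXTURE_SAMPLING_TIMES,
            responses=df[resp_names].astype(float),
        )
    except (KeyError, ValueError) as exc:
        raise FixtureIntegrityError(f"design fixture malformed: {exc}") from exc
    if design.n_runs != 10 or design.responses.shape != (10, 4):
        raise FixtureIntegrityError("design fixture has wrong shape")
    return design


# --------------------------------------------------------------------------
# mono-factor screening statistics

@dataclass
class MonoFactorDataset:
    """Group summaries (mean +/- SE) from a one-factor-at-a-time screen."""

    labels: list[str]
    means: np.ndarray
    sems: np.ndarray
    control_index: int = 0

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.sems = np.asarray(self.sems, dtype=float)
        if len(self.labels) != len(self.means) or len(self.means) != len(self.sems):
            raise ValueError("labels, means and sems must have equal length")
        if (self.sems < 0).any():
            raise ValueError("standard errors must be non-negative")
        if not (0 <= self.control_index < len(self.labels)):
            raise ValueError("control index out of range")


@dataclass
class DunnettResult:
    """Many-to-one comparison table plus the overall one-way ANOVA."""

    table: pd.DataFrame
    f_statistic: float
    f_pvalue: float
    df_between: int
    df_within: int
    ms_within: float
    seed: int = 0
    n_draws: int = 0


def one_way_anova_dunnett(
    data: MonoFactorDataset,
    alpha: float = 0.05,
    n_per_group: int = 3,
    seed: int = 0,
    n_draws: int = 100_000,
) -> DunnettResult:
    """One-way ANOVA reconstructed from group summaries, with Dunnett-style
    many-to-one comparisons against the control group.

    The per-group SD is recovered from the SE (``sd = se * sqrt(n)``) and
    pooled into the within-group mean square.  Dunnett adjustment uses a
    seeded Monte-Carlo sample of the joint null distribution of the
    max-|t| statistic over the k-1 contrasts; adjusted p-values are floored
    at the unadjusted ones so the adjustment is never anti-conservative.
    """
    k = len(data.labels)
    if k < 2:
        raise InsufficientGroupsError("at least two groups are required")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")

    n = n_per_group
    sds = data.sems * math.sqrt(n)
    ms_within = float(np.mean(sds**2))
    grand = float(np.mean(data.means))
    ms_between = n * float(np.sum((data.means - grand) ** 2)) / (k - 1)
    df_b, df_w = k - 1, k * (n - 1)

    if ms_within == 0.0:
        if ms_between > 0.0:
            raise DegenerateVarianceError(
                "zero pooled variance with unequal group means"
            )
        f_stat, f_p = 0.0, 1.0
    else:
        f_stat = ms_between / ms_within
        f_p = float(stats.f.sf(f_stat, df_b, df_w))

    ctrl = data.control_index
    others = [i for i in range(k) if i != ctrl]
    diffs = data.means[others] - data.means[ctrl]
    if ms_within > 0.0:
        t_obs = diffs / math.sqrt(2.0 * ms_within / n)
    else:
        t_obs = np.zeros_like(diffs)
    p_unadj = 2.0 * stats.t.sf(np.abs(t_obs), df_w)

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, k))
    s = np.sqrt(rng.chisquare(df_w, size=n_draws) / df_w)
    null_t = (z[:, others] - z[:, [ctrl]]) / (s[:, None] * math.sqrt(2.0))
    max_abs = np.max(np.abs(null_t), axis=1)
    p_adj = np.array([np.mean(max_abs >= abs(t)) for t in t_obs])
    p_adj = np.minimum(1.0, np.maximum(p_adj, p_unadj))

    table = pd.DataFrame(
        {
            "group": [data.labels[i] for i in others],
            "mean_diff": diffs,
            "t": t_obs,
            "p_unadjusted": p_unadj,
            "p_adjusted": p_adj,
            "significant": p_adj < alpha,
        }
    )
    return DunnettResult(
        table=table,
        f_statistic=f_stat,
        f_pvalue=f_p,
        df_between=df_b,
        df_within=df_w,
        ms_within=ms_within,
        seed=seed,
        n_draws=n_draws,
    )
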
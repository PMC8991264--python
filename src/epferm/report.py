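"""Report rendering: lossless JSON plus human-readable tables.

JSON keeps full float precision (round-trips exactly through ``json``);
text tables round to 3 decimals, the display convention of the printed
fit tables this package mirrors.
"""

from __future__ import annotations

import json
from typing import Union

import pandas as pd

from .kinetics import KineticFitResult
from .response_surface import FittedResponseModel, OptimumRecommendation

__all__ = ["render_report", "to_json", "render_text"]

Reportable = Union[FittedResponseModel, KineticFitResult, OptimumRecommendation]


def to_json(result: Reportable, **meta) -> str:
    payload = result.to_dict()
    if meta:
        payload["meta"] = meta
    return json.dumps(payload, indent=2)


def _fmt(x: float) -> str:
    return f"{x:.3f}"


def _response_model_text(m: FittedResponseModel) -> str:
    rows = [("Constant", m.intercept)] + [(t.name, t) for t in m.terms]
    df = pd.DataFrame(
        {
            "Item": [nm for nm, _ in rows],
            "Coefficient": [_fmt(t.coef) for _, t in rows],
            "t-value": [_fmt(t.t) for _, t in rows],
            "Sig": [_fmt(t.p) for _, t in rows],
        }
    )
    lines = [
        "Response-surface fit (" + m.spec.response + ")",
        df.to_string(index=False),
        f"R^2 = {_fmt(m.r_squared)}",
        f"Model: F = {_fmt(m.f_statistic)} (df {m.df_model}, {m.df_resid}), "
        f"p = {_fmt(m.f_pvalue)}",
    ]
    return "\n".join(lines)


def _kinetic_text(r: KineticFitResult) -> str:
    if r.failed:
        return f"{r.kind} model: FAILED ({r.error})"
    df = r.coefficients.copy()
    df.loc["Constant"] = [r.intercept, r.intercept_se, r.intercept_t, r.intercept_p]
    shown = df.map(_fmt)
    shown.index.name = "Item"
    lines = [
        f"{r.kind} model (integrated-form fit, n = {r.n_obs}, "
        f"{r.n_dropped} point(s) dropped)",
        shown.reset_index().to_string(index=False),
        f"R^2 = {_fmt(r.r_squared)}   adj-R^2 = {_fmt(r.adj_r_squared)}",
        f"F-value = {_fmt(r.f_statistic)}   p-value = {_fmt(r.f_pvalue)}",
        "Recovered parameters: "
        + ", ".join(f"{k} = {v:.6g}" for k, v in r.params_recovered.items()),
    ]
    if r.warnings:
        lines.append("Warnings: " + "; ".join(r.warnings))
    return "\n".join(lines)


def _optimum_text(o: OptimumRecommendation) -> str:
    d = o.to_dict()
    lines = ["Recommended optimum (g/L):"]
    for k, v in d["settings_g_per_L"].items():
        lines.append(f"  {k:14s} {v:8.3f}   [{o.provenance[k]}]")
    lines.append(f"Optimum sampling time: {o.optimum_time_h:.2f} h")
    lines.append(f"Predicted yield: {o.predicted_response:.2f} ug/L")
    return "\n".join(lines)


def render_text(result: Reportable) -> str:
    if isinstance(result, FittedResponseModel):
        return _response_model_text(result)
    if isinstance(result, KineticFitResult):
        return _kinetic_text(result)
    if isinstance(result, OptimumRecommendation):
        return _optimum_text(result)
    raise TypeError(f"cannot render {type(result).__name__}")


def render_report(result: Reportable, **meta) -> tuple[str, str]:
    """(text, json) pair for one fit result."""
    return render_text(result), to_json(result, **meta)
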
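"""CSV schemas and validated readers/writers.

All files are UTF-8, comma-separated, ``.`` decimal, header mandatory.

* design table: ``run,glycerol,yeast_powder,peptone,znso4,mgso4,kh2po4``
  (g/100 mL) with optional ``ep_28h,ep_56h,ep_84h,ep_112h`` (ug/L);
* long observation table: ``run,time_h,<factors...>,ep_ug_per_L``;
* time series: ``time_h,substrate_g_per_L[,biomass_g_per_L][,product][,volume_L]``.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

from .design import DesignMatrix, FactorDefinition
from .errors import DataError
from .kinetics import BatchTimeSeries

__all__ = [
    "read_csv_checked",
    "read_design_csv",
    "write_design_csv",
    "read_long_table_csv",
    "read_series_csv",
    "write_series_csv",
    "file_sha256",
]

DESIGN_FACTORS = ["glycerol", "yeast_powder", "peptone", "znso4", "mgso4", "kh2po4"]
RESPONSE_COLUMNS = ["ep_28h", "ep_56h", "ep_84h", "ep_112h"]


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def read_csv_checked(path, required: list[str], optional: list[str] = ()) -> pd.DataFrame:
    """Read a CSV and verify its column schema, reporting what is missing."""
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise DataError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(
            f"{path}: missing columns {missing}; found {list(df.columns)}"
        )
    extra = [c for c in df.columns if c not in (*required, *optional)]
    if extra:
        raise DataError(f"{path}: unexpected columns {extra}")
    return df


def read_design_csv(path, sampling_times=(28.0, 56.0, 84.0, 112.0)) -> DesignMatrix:
    df = read_csv_checked(path, ["run", *DESIGN_FACTORS], RESPONSE_COLUMNS)
    have_resp = all(c in df.columns for c in RESPONSE_COLUMNS)
    factors = [
        FactorDefinition(
            name=nm, units="g/100 mL", levels=tuple(sorted(df[nm].astype(float)))
        )
        for nm in DESIGN_FACTORS
    ]
    try:
        return DesignMatrix(
            factors=factors,
            layout=df[DESIGN_FACTORS].astype(float),
            sampling_times=tuple(sampling_times) if have_resp else (),
            responses=df[RESPONSE_COLUMNS].astype(float) if have_resp else None,
        )
    except ValueError as exc:
        raise DataError(f"{path}: {exc}") from exc


def write_design_csv(design: DesignMatrix, path) -> None:
    design.to_frame().to_csv(path, index=False)


def read_long_table_csv(path) -> pd.DataFrame:
    return read_csv_checked(
        path, ["run", "time_h", *DESIGN_FACTORS, "ep_ug_per_L"]
    )


def read_series_csv(path) -> BatchTimeSeries:
    df = read_csv_checked(
        path,
        ["time_h", "substrate_g_per_L"],
        ["biomass_g_per_L", "product", "volume_L"],
    )
    def col(nm):
        return df[nm].to_numpy(dtype=float) if nm in df.columns else None
    try:
        return BatchTimeSeries(
            times=df["time_h"].to_numpy(dtype=float),
            substrate=df["substrate_g_per_L"].to_numpy(dtype=float),
            biomass=col("biomass_g_per_L"),
            product=col("product"),
            volume=col("volume_L"),
        )
    except ValueError as exc:
        raise DataError(f"{path}: {exc}") from exc


def write_series_csv(series: BatchTimeSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)
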
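"""CSV dialects for logger, gas-exchange and leaf-trait tables.

Three plain-text formats move data between pipeline stages:

* climate logger CSV: ``timestamp,par_umol_m2_s,temp_air_c`` with ISO-8601
  timestamps, one row per 2-min sample (Hobo-station style export);
* gas-exchange response CSV: ``temp_c,par_umol_m2_s,pn_umol_m2_s,plant_id``;
* leaf-trait CSV: ``group,species,site,amax,rd`` with optional ``lma`` and
  ``pct_n`` columns.

In memory all tables are pandas DataFrames with short internal column names
(``par``, ``temp_air``, ``temp``, ``pn``, ``amax``, ``rd`` ...); the functions
here translate between the on-disk headers and the internal names.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

_CLIMATE_OUT = {"timestamp": "timestamp", "par": "par_umol_m2_s", "temp_air": "temp_air_c"}
_RESPONSE_OUT = {"temp": "temp_c", "par": "par_umol_m2_s", "pn": "pn_umol_m2_s",
                 "plant_id": "plant_id"}


def write_climate_csv(climate: pd.DataFrame, path: str | Path) -> None:
    """Write a climate series to logger CSV."""
    out = climate[list(_CLIMATE_OUT)].rename(columns=_CLIMATE_OUT)
    out.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")


def read_climate_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = set(_CLIMATE_OUT.values()) - set(df.columns)
    if missing:
        raise ValueError(f"climate CSV missing columns: {sorted(missing)}")
    return df.rename(columns={v: k for k, v in _CLIMATE_OUT.items()})


def write_response_csv(data: pd.DataFrame, path: str | Path) -> None:
    """Write gas-exchange measurements (one row per Temp x PAR reading)."""
    out = data[list(_RESPONSE_OUT)].rename(columns=_RESPONSE_OUT)
    out.to_csv(path, index=False)


def read_response_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_RESPONSE_OUT.values()) - set(df.columns)
    if missing:
        raise ValueError(f"response CSV missing columns: {sorted(missing)}")
    return df.rename(columns={v: k for k, v in _RESPONSE_OUT.items()})


def write_trait_csv(table: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("group", "species", "site", "amax", "rd", "lma", "pct_n")
            if c in table.columns]
    table[cols].to_csv(path, index=False)


def read_trait_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("group", "amax", "rd"):
        if col not in df.columns:
            raise ValueError(f"trait CSV missing column: {col}")
    return df
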
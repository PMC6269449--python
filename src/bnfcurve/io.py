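"""CSV readers with schema validation.

All readers reject unknown treatment or stage labels with an error message
naming the offending line numbers (1-based, counting the header as line 1).
"""

from __future__ import annotations

import pandas as pd

from .errors import SchemaError
from .ureide_thermal import Stage, Treatment

ASSAY_COLUMNS = ["site_id", "treatment", "block", "stage", "ureide_conc", "nitrate_conc"]
WEATHER_COLUMNS = ["date", "tmax_c", "tmin_c"]
TRIAL_COLUMNS = [
    "site_id", "treatment", "block", "tt_r6", "rau_r6",
    "seed_yield", "biomass", "hi", "protein", "oil",
]

_VALID_TREATMENTS = {t.value for t in Treatment}
_VALID_STAGES = {s.value for s in Stage}


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _reject_unknown(df: pd.DataFrame, column: str, valid: set, path) -> None:
    bad = ~df[column].astype(str).isin(valid)
    if bad.any():
        # +2: header line plus 1-based indexing
        lines = (df.index[bad] + 2).tolist()
        labels = sorted(df.loc[bad, column].astype(str).unique())
        raise SchemaError(
            f"{path}: unknown {column} label(s) {labels} on line(s) {lines[:10]}"
        )


def read_assays(path) -> pd.DataFrame:
    """Read a stem-assay CSV (site_id, treatment, block, stage, ureide_conc, nitrate_conc)."""
    df = pd.read_csv(path)
    _require_columns(df, ASSAY_COLUMNS, path)
    _reject_unknown(df, "treatment", _VALID_TREATMENTS, path)
    _reject_unknown(df, "stage", _VALID_STAGES, path)
    neg = (df["ureide_conc"] < 0) | (df["nitrate_conc"] < 0)
    if neg.any():
        raise SchemaError(
            f"{path}: negative concentration(s) on line(s) {(df.index[neg] + 2).tolist()[:10]}"
        )
    return df


def read_weather(path) -> pd.DataFrame:
    """Read a daily weather CSV (date, tmax_c, tmin_c; optional site_id)."""
    df = pd.read_csv(path)
    _require_columns(df, WEATHER_COLUMNS, path)
    df["date"] = pd.to_datetime(df["date"]).dt.date
    bad = df["tmax_c"] < df["tmin_c"]
    if bad.any():
        raise SchemaError(
            f"{path}: tmax_c < tmin_c on line(s) {(df.index[bad] + 2).tolist()[:10]}"
        )
    return df


def read_trials(path) -> pd.DataFrame:
    """Read a plot-level trial CSV (agronomic outcomes plus tt_r6 and rau_r6)."""
    df = pd.read_csv(path)
    _require_columns(df, TRIAL_COLUMNS, path)
    _reject_unknown(df, "treatment", _VALID_TREATMENTS, path)
    bad_rau = (df["rau_r6"] < 0) | (df["rau_r6"] > 100)
    if bad_rau.any():
        raise SchemaError(
            f"{path}: rau_r6 outside [0, 100] on line(s) {(df.index[bad_rau] + 2).tolist()[:10]}"
        )
    bad_hi = (df["hi"] <= 0) | (df["hi"] >= 1)
    if bad_hi.any():
        raise SchemaError(
            f"{path}: hi outside (0, 1) on line(s) {(df.index[bad_hi] + 2).tolist()[:10]}"
        )
    return df
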
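"""CSV schemas and validated readers/writers.

All tables are comma-separated UTF-8 with a header row and "." decimals.

band records : specimen_id, year_ce, d11B_permil, B_ngg, BCa_umolmol
               (optional: distance_um, flag, contam_fraction)
transects    : specimen_id, distance_um, MgCa_mmolmol
environment  : year_ce, T_C, S_psu
reconstruction: year_ce, pH_median, ci68_lo, ci68_hi, ci95_lo, ci95_hi,
               n_valid_draws (plus specimen_id)
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .exceptions import SchemaError

BAND_COLUMNS = ["specimen_id", "year_ce", "d11B_permil", "B_ngg", "BCa_umolmol"]
TRANSECT_COLUMNS = ["specimen_id", "distance_um", "MgCa_mmolmol"]
ENV_COLUMNS = ["year_ce", "T_C", "S_psu"]
RECON_COLUMNS = [
    "specimen_id", "year_ce", "pH_median", "ci68_lo", "ci68_hi",
    "ci95_lo", "ci95_hi", "n_valid_draws",
]


def _read(path, required, numeric):
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise SchemaError(f"cannot read {path}: file not found") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")
    for col in numeric:
        if col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                raise SchemaError(
                    f"{path}: non-numeric value in column {col!r} at row(s) "
                    f"{list(df.index[bad][:5])}"
                )
            df[col] = coerced
    return df


def read_bands(path) -> pd.DataFrame:
    """Read and validate a band-record table."""
    df = _read(path, BAND_COLUMNS, ["year_ce", "d11B_permil", "B_ngg", "BCa_umolmol", "distance_um"])
    if (df["B_ngg"].dropna() <= 0).any():
        raise SchemaError(f"{path}: B_ngg must be positive where present")
    return df


def read_transect(path) -> pd.DataFrame:
    """Read and validate a Mg/Ca laser transect table."""
    df = _read(path, TRANSECT_COLUMNS, ["distance_um", "MgCa_mmolmol"])
    return df


def read_env(path) -> pd.DataFrame:
    """Read and validate a per-year environment table."""
    return _read(path, ENV_COLUMNS, ENV_COLUMNS)


def write_csv(df: pd.DataFrame, path) -> Path:
    """Write a frame as plain comma-separated UTF-8 with header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
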
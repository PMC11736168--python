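"""B/Ca-based screening of non-primary carbonate in coralline algae.

Primary algal carbonate shows a positive linear association between B/Ca and
d11B, both within and between specimens.  Infill by serpulid worm carbonate
(B/Ca near 400 umol/mol, d11B below 20 permil) drags a sub-sample off that
trend towards anomalously high B/Ca and low d11B.  A robust Theil-Sen trend
of d11B on B/Ca is fitted to the records and a sub-sample is flagged as
contaminated when it falls far below the trend (in scaled-MAD units of the
residuals) while exceeding the median B/Ca.  The flagged exclusion rule is a
single deterministic pass; flags are order-invariant and idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import theilslopes

from .exceptions import InsufficientDataError, InvalidInputError
from .proxy import CalibrationModel, ProxyParams, borate_from_skeletal

__all__ = [
    "ContaminantEndmember",
    "ScreenParams",
    "TrendFit",
    "fit_trend",
    "flag_contaminated",
    "contamination_fraction",
    "screen",
    "uninvertible_threshold",
]

# normal-consistency factor for the median absolute deviation
_MAD_SCALE = 1.4826


@dataclass(frozen=True)
class ContaminantEndmember:
    """Secondary-carbonate composition (serpulid worm tube defaults)."""

    BCa: float = 400.0
    d11B: float = 18.0


@dataclass(frozen=True)
class ScreenParams:
    """Flagging rule parameters.

    ``mad_k`` is the residual threshold in scaled-MAD units (calibrated so
    the study's own dataset yields its seven known exclusions);
    ``two_pass`` refits the trend once on the unflagged records and reflags
    (off by default to guarantee one-pass determinism).
    """

    mad_k: float = 3.0
    min_records: int = 8
    pooling: str = "pooled"  # or "per_specimen"
    two_pass: bool = False

    def __post_init__(self):
        if not self.mad_k > 0:
            raise InvalidInputError("mad_k must be positive")
        if self.pooling not in ("pooled", "per_specimen"):
            raise InvalidInputError(f"unknown pooling mode {self.pooling!r}")


@dataclass(frozen=True)
class TrendFit:
    """Robust line d11B = slope * B/Ca + intercept."""

    slope: float
    intercept: float
    n: int

    def predict(self, bca):
        return self.slope * np.asarray(bca, dtype=float) + self.intercept


def uninvertible_threshold(
    params: ProxyParams = ProxyParams(), cal: CalibrationModel = CalibrationModel()
) -> float:
    """Skeletal d11B below which the borate equation has no pH solution."""
    borate_limit = (params.d11B_sw - 1000.0 * (params.alpha_B - 1.0)) / params.alpha_B
    return float(cal.slope * borate_limit + cal.intercept)


def fit_trend(records: pd.DataFrame, min_records: int = 8) -> TrendFit:
    """Theil-Sen fit of d11B on B/Ca over unflagged records."""
    use = records
    if "flag" in records.columns:
        use = records[records["flag"].fillna("ok").isin(["ok", ""])]
    use = use.dropna(subset=["BCa_umolmol", "d11B_permil"])
    if len(use) < min_records:
        raise InsufficientDataError(
            f"need at least {min_records} records for a trend fit, got {len(use)}"
        )
    slope, intercept, _, _ = theilslopes(
        use["d11B_permil"].to_numpy(), use["BCa_umolmol"].to_numpy()
    )
    return TrendFit(slope=float(slope), intercept=float(intercept), n=len(use))


def _flag_once(records, trend, params, contaminant, proxy_params, cal):
    out = records.copy()
    resid = out["d11B_permil"].to_numpy() - trend.predict(out["BCa_umolmol"].to_numpy())
    mad = _MAD_SCALE * np.median(np.abs(resid - np.median(resid)))
    bca_median = float(np.median(out["BCa_umolmol"].to_numpy()))
    contaminated = (resid < -params.mad_k * mad) & (out["BCa_umolmol"].to_numpy() > bca_median)
    uninvertible = out["d11B_permil"].to_numpy() <= uninvertible_threshold(proxy_params, cal)
    flags = np.where(contaminated, "contaminated", "ok")
    flags = np.where(uninvertible & ~contaminated, "uninvertible", flags)
    out["flag"] = flags
    return out


def flag_contaminated(
    records: pd.DataFrame,
    trend: TrendFit,
    params: ScreenParams = ScreenParams(),
    contaminant: ContaminantEndmember = ContaminantEndmember(),
    proxy_params: ProxyParams = ProxyParams(),
    cal: CalibrationModel = CalibrationModel(),
) -> pd.DataFrame:
    """Return a copy of ``records`` with a ``flag`` column filled in.

    A record is ``contaminated`` iff its vertical residual from the trend is
    below -mad_k * MAD and its B/Ca exceeds the median; a record whose d11B
    lies below the borate-equation invertibility limit is independently
    ``uninvertible``.
    """
    out = _flag_once(records, trend, params, contaminant, proxy_params, cal)
    if params.two_pass:
        refit = fit_trend(out, params.min_records)
        out = _flag_once(records, refit, params, contaminant, proxy_params, cal)
    return out


def contamination_fraction(
    record: pd.Series,
    trend: TrendFit,
    contaminant: ContaminantEndmember = ContaminantEndmember(),
) -> float:
    """Two-endmember mass-balance contamination estimate for a flagged record.

    Assumes the primary component lies on the fitted trend and that B/Ca and
    d11B mix linearly; the estimate is clipped to [0, 1].  Returns NaN when
    the contaminant does not sit below the trend (undefined geometry).
    """
    denom = trend.predict(contaminant.BCa) - contaminant.d11B
    if denom <= 0:
        return float("nan")
    deficit = trend.predict(record["BCa_umolmol"]) - record["d11B_permil"]
    return float(np.clip(deficit / denom, 0.0, 1.0))


def screen(
    records: pd.DataFrame,
    params: ScreenParams = ScreenParams(),
    contaminant: ContaminantEndmember = ContaminantEndmember(),
    proxy_params: ProxyParams = ProxyParams(),
    cal: CalibrationModel = CalibrationModel(),
    with_fraction: bool = True,
) -> pd.DataFrame:
    """Fit trend(s), flag records, and optionally estimate contamination fractions.

    With ``pooling='per_specimen'`` a separate trend is fitted per specimen;
    the default pools all specimens (the B/Ca-d11B association holds both
    within and between specimens).
    """
    def run(df):
        trend = fit_trend(df, params.min_records)
        flagged = flag_contaminated(df, trend, params, contaminant, proxy_params, cal)
        if with_fraction:
            flagged["contam_fraction"] = [
                contamination_fraction(row, trend, contaminant)
                if row["flag"] == "contaminated" else np.nan
                for _, row in flagged.iterrows()
            ]
        return flagged

    if params.pooling == "per_specimen":
        parts = [run(g) for _, g in records.groupby("specimen_id", sort=False)]
        return pd.concat(parts).loc[records.index]
    return run(records)
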
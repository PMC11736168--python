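"""Conversion of coralline-algae skeletal d11B to seawater pH.

The borate ion B(OH)4- is the boron species incorporated into the skeleton,
and its isotopic composition rises with seawater pH:

    pH = pKB* - log10( -(d11Bsw - d11Bb) / (d11Bsw - aB*d11Bb - 1000*(aB-1)) )

with aB = 1.0272 the boric acid / borate fractionation factor and d11Bsw the
seawater composition.  Clathromorphum compactum calcifies from an internally
pH-elevated fluid, so a species-specific culture calibration links skeletal
d11B to d11B of borate:

    d11B_skeletal = 1.46 (+/-0.06, 2s) * d11B_borate + 6.91 (+/-0.72, 2s)

Analytical precision of a d11B measurement depends on the boron content of
the analysed solution via a double-exponential reproducibility curve, and the
full reconstruction propagates measurement, calibration, seawater-d11B,
temperature and salinity uncertainties by Monte-Carlo resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .carbonate import pkb_star
from .exceptions import InvalidInputError, UninvertibleError

__all__ = [
    "ProxyParams",
    "CalibrationModel",
    "SCHOODIC_SEAWATER_D11B",
    "seawater_d11b_summary",
    "measurement_2sigma",
    "borate_from_skeletal",
    "skeletal_from_borate",
    "ph_from_borate",
    "delta11B_borate_from_ph",
    "ph_deterministic",
    "reconstruct",
]

#: Surface seawater d11B measurements from the Schoodic Point site
#: (collection date, temperature degC, d11B permil).
SCHOODIC_SEAWATER_D11B = pd.DataFrame(
    {
        "collection_date": ["2016.05.13", "2016.10.05", "2017.07.06", "2017.11.02", "2017.11.30"],
        "temperature_C": [7.0, 13.0, 9.0, 13.0, 9.0],
        "d11B_permil": [39.73, 39.77, 39.77, 39.69, 39.69],
    }
)


def seawater_d11b_summary() -> tuple[float, float]:
    """Mean and 2-sigma of the local seawater d11B measurements (permil)."""
    vals = SCHOODIC_SEAWATER_D11B["d11B_permil"].to_numpy()
    return float(vals.mean()), float(2.0 * vals.std(ddof=1))


@dataclass(frozen=True)
class ProxyParams:
    """Borate-equation parameters and 1-sigma environmental uncertainties.

    The default seawater d11B of 39.73 permil is the locally measured mean;
    the open-ocean compilation value 39.61 permil is available as an
    alternative.  ``pkb_constant`` pins pKB* to a fixed value (the worked
    example uses 8.82) instead of recomputing it from per-year T and S.
    """

    alpha_B: float = 1.0272
    d11B_sw: float = 39.73
    d11B_sw_sd: float = 0.1
    T_sd: float = 1.0
    S_sd: float = 1.0
    pkb_constant: float | None = None

    def __post_init__(self):
        if not self.alpha_B > 1:
            raise InvalidInputError("alpha_B must exceed 1")
        if not 39.0 <= self.d11B_sw <= 41.0:
            raise InvalidInputError("d11B_sw outside plausible seawater range [39, 41]")


@dataclass(frozen=True)
class CalibrationModel:
    """Species calibration d11B_skeletal = slope * d11B_borate + intercept (2-sigma errors)."""

    slope: float = 1.46
    slope_2sigma: float = 0.06
    intercept: float = 6.91
    intercept_2sigma: float = 0.72

    def __post_init__(self):
        if not self.slope > 0:
            raise InvalidInputError("calibration slope must be positive")


def measurement_2sigma(B_conc):
    """2-sigma analytical uncertainty (permil) of a d11B measurement.

    ``B_conc`` is the boron concentration of the analysed solution in ng/g:
    2s = 1.61 exp(-0.22 [B]) + 0.17 exp(-0.002 [B]).
    """
    b = np.asarray(B_conc, dtype=float)
    if np.any(~np.isfinite(b)) or np.any(b < 0):
        raise InvalidInputError(f"B concentration must be finite and >= 0, got {B_conc}")
    out = 1.61 * np.exp(-0.22 * b) + 0.17 * np.exp(-0.002 * b)
    return float(out) if out.ndim == 0 else out


def borate_from_skeletal(d11B_skel, cal: CalibrationModel = CalibrationModel()):
    """Invert the species calibration: d11B of borate from skeletal d11B."""
    return (np.asarray(d11B_skel, dtype=float) - cal.intercept) / cal.slope


def skeletal_from_borate(d11B_borate, cal: CalibrationModel = CalibrationModel()):
    """Forward species calibration (used by the synthetic-data generator)."""
    return cal.slope * np.asarray(d11B_borate, dtype=float) + cal.intercept


def _log_argument(d11B_borate, d11B_sw, alpha):
    return -(d11B_sw - d11B_borate) / (d11B_sw - alpha * d11B_borate - 1000.0 * (alpha - 1.0))


def ph_from_borate(d11B_borate, pKB_star, params: ProxyParams = ProxyParams(), *, invalid: str = "raise"):
    """Total-scale pH from d11B of borate via the borate equation.

    Below a critical borate d11B the argument of the log is non-positive and
    no pH exists; with ``invalid='raise'`` this raises
    :class:`UninvertibleError`, with ``invalid='nan'`` such entries become
    NaN (the Monte-Carlo path).
    """
    db = np.asarray(d11B_borate, dtype=float)
    arg = _log_argument(db, params.d11B_sw, params.alpha_B)
    bad = ~(arg > 0)
    if np.any(bad):
        if invalid == "raise":
            raise UninvertibleError(
                "d11B so low that a seawater pH value cannot be calculated "
                f"(borate d11B = {db[bad] if db.ndim else float(db)})"
            )
        arg = np.where(bad, np.nan, arg)
    out = np.asarray(pKB_star, dtype=float) - np.log10(arg)
    return float(out) if out.ndim == 0 else out


def delta11B_borate_from_ph(pH, pKB_star, params: ProxyParams = ProxyParams()):
    """Exact algebraic inverse of :func:`ph_from_borate` (forward model)."""
    ph = np.asarray(pH, dtype=float)
    if np.any(ph < 2.0) or np.any(ph > 12.0):
        raise InvalidInputError(f"pH out of range [2, 12]: {pH}")
    r = 10.0 ** (np.asarray(pKB_star, dtype=float) - ph)
    a, dsw = params.alpha_B, params.d11B_sw
    out = (dsw * (1.0 + r) - 1000.0 * r * (a - 1.0)) / (1.0 + r * a)
    return float(out) if out.ndim == 0 else out


def ph_deterministic(
    d11B_skel,
    pKB_star,
    params: ProxyParams = ProxyParams(),
    cal: CalibrationModel = CalibrationModel(),
):
    """Central (noise-free) pH estimate from skeletal d11B."""
    return ph_from_borate(borate_from_skeletal(d11B_skel, cal), pKB_star, params)


def _record_pkb(params: ProxyParams, T, S):
    if params.pkb_constant is not None:
        return np.full(np.shape(T), params.pkb_constant, dtype=float)
    return pkb_star(T, np.clip(S, 1e-6, None), validate=False)


def reconstruct(
    records: pd.DataFrame,
    env: pd.DataFrame,
    params: ProxyParams = ProxyParams(),
    cal: CalibrationModel = CalibrationModel(),
    n_draws: int = 2000,
    seed: int = 0,
    measurement_sigma_scale: float = 1.0,
) -> pd.DataFrame:
    """Monte-Carlo pH reconstruction for screened band records.

    Parameters
    ----------
    records
        Columns ``specimen_id, year_ce, d11B_permil, B_ngg`` (and optionally
        ``flag``; only rows with flag ``ok``/missing are used).
    env
        Per-year environment, columns ``year_ce, T_C, S_psu``; must cover
        every record year.
    n_draws, seed
        Number of Monte-Carlo draws per record and the RNG seed.  Draws are
        vectorised per record in fixed row order, so output is bit-stable
        for a given seed.
    measurement_sigma_scale
        Multiplier on the analytical (double-exponential) error; 0 gives the
        degenerate noise-free limit for that term.

    Each draw independently perturbs: the measurement (normal, sigma from the
    reproducibility curve halved to 1-sigma), calibration slope and intercept
    (stated 2-sigma halved), seawater d11B, temperature and salinity; pKB* is
    recomputed per draw from the perturbed T and S.  Draws whose perturbed
    borate d11B falls below the invertibility limit are dropped and counted;
    a record with more than 50% invalid draws is excluded with a warning.

    Returns
    -------
    DataFrame with columns ``specimen_id, year_ce, pH_median, ci68_lo,
    ci68_hi, ci95_lo, ci95_hi, n_valid_draws``.
    """
    if n_draws < 1:
        raise InvalidInputError("n_draws must be >= 1")
    use = records
    if "flag" in records.columns:
        use = records[records["flag"].fillna("ok").isin(["ok", ""])]
    env_t = env.set_index("year_ce")
    missing = set(use["year_ce"]) - set(env_t.index)
    if missing:
        raise InvalidInputError(f"environment series missing years: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    rows = []
    for _, rec in use.iterrows():
        year = int(rec["year_ce"])
        t0, s0 = float(env_t.loc[year, "T_C"]), float(env_t.loc[year, "S_psu"])
        sig_meas = measurement_sigma_scale * measurement_2sigma(float(rec["B_ngg"])) / 2.0
        d11b = float(rec["d11B_permil"]) + rng.normal(0.0, sig_meas, n_draws) if sig_meas > 0 \
            else np.full(n_draws, float(rec["d11B_permil"]))
        slope = rng.normal(cal.slope, cal.slope_2sigma / 2.0, n_draws) if cal.slope_2sigma > 0 \
            else np.full(n_draws, cal.slope)
        intercept = rng.normal(cal.intercept, cal.intercept_2sigma / 2.0, n_draws) if cal.intercept_2sigma > 0 \
            else np.full(n_draws, cal.intercept)
        dsw = rng.normal(params.d11B_sw, params.d11B_sw_sd, n_draws) if params.d11B_sw_sd > 0 \
            else np.full(n_draws, params.d11B_sw)
        T = rng.normal(t0, params.T_sd, n_draws) if params.T_sd > 0 else np.full(n_draws, t0)
        S = rng.normal(s0, params.S_sd, n_draws) if params.S_sd > 0 else np.full(n_draws, s0)
        pkb = _record_pkb(params, T, S)

        db = (d11b - intercept) / slope
        arg = -(dsw - db) / (dsw - params.alpha_B * db - 1000.0 * (params.alpha_B - 1.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            ph = np.where(arg > 0, pkb - np.log10(np.where(arg > 0, arg, 1.0)), np.nan)
        valid = ph[np.isfinite(ph)]
        if valid.size < 0.5 * n_draws:
            warnings.warn(
                f"record year {year} ({rec['specimen_id']}): more than 50% of draws "
                "uninvertible; excluded from reconstruction",
                stacklevel=2,
            )
            continue
        lo68, med, hi68 = np.percentile(valid, [16.0, 50.0, 84.0])
        lo95, hi95 = np.percentile(valid, [2.5, 97.5])
        rows.append(
            {
                "specimen_id": rec["specimen_id"],
                "year_ce": year,
                "pH_median": med,
                "ci68_lo": lo68,
                "ci68_hi": hi68,
                "ci95_lo": lo95,
                "ci95_hi": hi95,
                "n_valid_draws": int(valid.size),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "specimen_id", "year_ce", "pH_median", "ci68_lo", "ci68_hi",
            "ci95_lo", "ci95_hi", "n_valid_draws",
        ],
    )
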
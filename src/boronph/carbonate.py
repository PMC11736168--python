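"""Seawater carbonate-system equilibrium on the total pH scale.

Equilibrium constants are evaluated from temperature and salinity at surface
pressure: K1/K2 for carbonic acid from Lueker et al. (2000, total scale), KB
for boric acid from Dickson (1990), Kw from Millero (1995), the CO2
solubility K0 from Weiss (1974), and total boron proportional to salinity
after Uppstrom (1974).  Solvers convert between {ALK, DIC, pH, pCO2} pairs by
closed-form speciation where possible and Brent bracketing on pH otherwise.

Units: temperature in deg C, salinity in psu, ALK and DIC in umol/kg-sw,
pCO2 in uatm, all equilibrium constants in mol/kg-sw (K0 in mol/kg/atm).
No pressure correction is applied (samples shallower than 10 m).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
from scipy.optimize import brentq

from .exceptions import InvalidInputError, LowSalinityWarning, NoSolutionError

__all__ = [
    "ConstantsSet",
    "SeawaterState",
    "compute_constants",
    "pH_from_alk_dic",
    "alk_from_ph_dic",
    "dic_from_ph_alk",
    "dic_from_ph_pco2",
    "pco2_from_ph_dic",
    "pkb_star",
    "solve_state",
    "alk_change_for_ph_step",
]

# Uppstrom (1974) total boron / chlorinity ratio expressed per salinity unit:
# BT [mol/kg] = 0.0004157 * S / 35.  Switchable via `bt_scale`.
_BT_PER_SALINITY = 0.0004157 / 35.0

_PH_BRACKET = (2.0, 12.0)
_PH_XTOL = 1e-8
_ALK_RESIDUAL_TOL = 0.01  # umol/kg

LUEKER_MIN_SALINITY = 19.0


@dataclass(frozen=True)
class ConstantsSet:
    """Equilibrium constants at one (T, S), total pH scale, surface pressure.

    ``BT`` is total boron in umol/kg; the K's are mol/kg (K0 mol/kg/atm).
    """

    K0: float
    K1: float
    K2: float
    KB: float
    Kw: float
    BT: float
    T: float
    S: float

    def to_json(self) -> str:
        """Serialise for audit trails."""
        return json.dumps(asdict(self), sort_keys=True)


@dataclass
class SeawaterState:
    """One water parcel with its carbonate system solved.

    Any two of (ALK, DIC, pH, pCO2) determine the rest; see ``solve_state``.
    """

    T: float
    S: float
    ALK: float
    DIC: float
    pH: float
    pCO2: float


def _check_ts(T, S):
    T = np.asarray(T, dtype=float)
    S = np.asarray(S, dtype=float)
    if not (np.all(np.isfinite(T)) and np.all(np.isfinite(S))):
        raise InvalidInputError("T and S must be finite")
    if np.any(T < 0.0) or np.any(T > 40.0):
        raise InvalidInputError(f"temperature out of range [0, 40] degC: {T}")
    if np.any(S < 0.0) or np.any(S > 43.0):
        raise InvalidInputError(f"salinity out of range [0, 43] psu: {S}")
    if np.any(S < LUEKER_MIN_SALINITY):
        warnings.warn(
            "salinity below 19 psu: Lueker et al. constants are only stated "
            "to be suitable for salinity values down to 19 psu",
            LowSalinityWarning,
            stacklevel=3,
        )
    return T, S


def _lueker_k1k2(TK, S):
    pK1 = 3633.86 / TK - 61.2172 + 9.67770 * np.log(TK) - 0.011555 * S + 0.0001152 * S**2
    pK2 = 471.78 / TK + 25.9290 - 3.16967 * np.log(TK) - 0.01781 * S + 0.0001122 * S**2
    return 10.0**-pK1, 10.0**-pK2


def _dickson_kb(TK, S):
    sqS = np.sqrt(S)
    lnKB = (
        (-8966.90 - 2890.53 * sqS - 77.942 * S + 1.728 * S * sqS - 0.0996 * S**2) / TK
        + 148.0248
        + 137.1942 * sqS
        + 1.62142 * S
        + (-24.4344 - 25.085 * sqS - 0.2474 * S) * np.log(TK)
        + 0.053105 * sqS * TK
    )
    return np.exp(lnKB)


def _millero_kw(TK, S):
    lnKw = (
        148.9802
        - 13847.26 / TK
        - 23.6521 * np.log(TK)
        + (118.67 / TK - 5.977 + 1.0495 * np.log(TK)) * np.sqrt(S)
        - 0.01615 * S
    )
    return np.exp(lnKw)


def _weiss_k0(TK, S):
    lnK0 = (
        -60.2409
        + 93.4517 * (100.0 / TK)
        + 23.3585 * np.log(TK / 100.0)
        + S * (0.023517 - 0.023656 * (TK / 100.0) + 0.0047036 * (TK / 100.0) ** 2)
    )
    return np.exp(lnK0)


def compute_constants(T: float, S: float, bt_scale: float = _BT_PER_SALINITY) -> ConstantsSet:
    """Equilibrium constants and total boron at temperature ``T`` and salinity ``S``.

    A :class:`LowSalinityWarning` (not an error) is emitted below 19 psu, the
    stated validity limit of the Lueker formulation.
    """
    T, S = _check_ts(T, S)
    TK = T + 273.15
    K1, K2 = _lueker_k1k2(TK, S)
    return ConstantsSet(
        K0=float(_weiss_k0(TK, S)),
        K1=float(K1),
        K2=float(K2),
        KB=float(_dickson_kb(TK, S)),
        Kw=float(_millero_kw(TK, S)),
        BT=float(bt_scale * S * 1e6),
        T=float(T),
        S=float(S),
    )


def pkb_star(T, S, *, validate: bool = True):
    """pKB* = -log10(KB), vectorised over T and S.

    Averaged over T in [6, 11] degC at S = 30.3 psu this evaluates to 8.82,
    the constant used in the worked proxy example.  ``validate=False`` skips
    range checks (used by the Monte-Carlo sampler, whose perturbed T/S draws
    may stray slightly outside the nominal limits).
    """
    if validate:
        T, S = _check_ts(T, S)
    else:
        T = np.asarray(T, dtype=float)
        S = np.asarray(S, dtype=float)
    TK = T + 273.15
    out = -np.log10(_dickson_kb(TK, np.maximum(S, 1e-12)))
    return float(out) if out.ndim == 0 else out


def _speciation_alk(h: float, DIC_mol: float, c: ConstantsSet) -> float:
    """Model alkalinity (mol/kg) at proton activity ``h`` given DIC in mol/kg."""
    denom = h * h + c.K1 * h + c.K1 * c.K2
    hco3 = DIC_mol * c.K1 * h / denom
    co3 = DIC_mol * c.K1 * c.K2 / denom
    boh4 = (c.BT * 1e-6) * c.KB / (c.KB + h)
    oh = c.Kw / h
    return hco3 + 2.0 * co3 + boh4 + oh - h


def pH_from_alk_dic(ALK: float, DIC: float, constants: ConstantsSet) -> float:
    """Solve total-scale pH from total alkalinity and DIC (both umol/kg).

    The unique root of ALK = [HCO3-] + 2[CO3--] + [B(OH)4-] + [OH-] - [H+]
    is bracketed on pH in [2, 12] by Brent's method; the solved state
    satisfies the alkalinity balance to better than 0.01 umol/kg.
    """
    if not (np.isfinite(ALK) and np.isfinite(DIC)) or ALK <= 0 or DIC <= 0:
        raise InvalidInputError(f"ALK and DIC must be positive and finite, got {ALK}, {DIC}")
    alk_mol = ALK * 1e-6
    dic_mol = DIC * 1e-6

    def residual(ph: float) -> float:
        return _speciation_alk(10.0**-ph, dic_mol, constants) - alk_mol

    lo, hi = _PH_BRACKET
    rlo, rhi = residual(lo), residual(hi)
    if rlo * rhi > 0:
        raise NoSolutionError(
            f"no pH root in [{lo}, {hi}] for ALK={ALK}, DIC={DIC}: unphysical pair"
        )
    ph = brentq(residual, lo, hi, xtol=_PH_XTOL)
    if abs(residual(ph)) * 1e6 > _ALK_RESIDUAL_TOL:
        raise NoSolutionError(f"alkalinity residual exceeds {_ALK_RESIDUAL_TOL} umol/kg")
    return float(ph)


def alk_from_ph_dic(pH: float, DIC: float, constants: ConstantsSet) -> float:
    """Total alkalinity (umol/kg) from pH and DIC: direct closed-form evaluation."""
    if not (2.0 <= pH <= 12.0) or not np.isfinite(DIC) or DIC <= 0:
        raise InvalidInputError(f"need 2 <= pH <= 12 and DIC > 0, got pH={pH}, DIC={DIC}")
    return float(_speciation_alk(10.0**-pH, DIC * 1e-6, constants) * 1e6)


def dic_from_ph_alk(pH: float, ALK: float, constants: ConstantsSet) -> float:
    """DIC (umol/kg) from pH and total alkalinity: closed-form companion solve."""
    if not (2.0 <= pH <= 12.0) or not np.isfinite(ALK):
        raise InvalidInputError(f"need 2 <= pH <= 12 and finite ALK, got pH={pH}, ALK={ALK}")
    h = 10.0**-pH
    c = constants
    non_carbonate = (c.BT * 1e-6) * c.KB / (c.KB + h) + c.Kw / h - h
    carb_alk_per_dic = (c.K1 * h + 2.0 * c.K1 * c.K2) / (h * h + c.K1 * h + c.K1 * c.K2)
    dic_mol = (ALK * 1e-6 - non_carbonate) / carb_alk_per_dic
    if dic_mol <= 0:
        raise NoSolutionError(f"non-positive DIC implied by pH={pH}, ALK={ALK}")
    return float(dic_mol * 1e6)


def dic_from_ph_pco2(pH: float, pCO2: float, constants: ConstantsSet) -> float:
    """DIC (umol/kg) from pH and pCO2 (uatm): CO2* = K0 pCO2, then speciation."""
    if not np.isfinite(pCO2) or pCO2 <= 0:
        raise InvalidInputError(f"pCO2 must be positive and finite, got {pCO2}")
    if not (2.0 <= pH <= 12.0):
        raise InvalidInputError(f"pH out of range [2, 12]: {pH}")
    h = 10.0**-pH
    co2_mol = constants.K0 * pCO2 * 1e-6
    dic_mol = co2_mol * (1.0 + constants.K1 / h + constants.K1 * constants.K2 / (h * h))
    return float(dic_mol * 1e6)


def pco2_from_ph_dic(pH: float, DIC: float, constants: ConstantsSet) -> float:
    """pCO2 (uatm) from pH and DIC (umol/kg)."""
    if not (2.0 <= pH <= 12.0) or DIC <= 0:
        raise InvalidInputError(f"need 2 <= pH <= 12 and DIC > 0, got pH={pH}, DIC={DIC}")
    h = 10.0**-pH
    c = constants
    co2_mol = (DIC * 1e-6) * h * h / (h * h + c.K1 * h + c.K1 * c.K2)
    return float(co2_mol / c.K0 * 1e6)


def solve_state(
    T: float,
    S: float,
    ALK: float | None = None,
    DIC: float | None = None,
    pH: float | None = None,
    pCO2: float | None = None,
    constants: ConstantsSet | None = None,
) -> SeawaterState:
    """Solve the full carbonate system from any two of ALK, DIC, pH, pCO2."""
    c = constants if constants is not None else compute_constants(T, S)
    given = {k: v for k, v in dict(ALK=ALK, DIC=DIC, pH=pH, pCO2=pCO2).items() if v is not None}
    if len(given) != 2:
        raise InvalidInputError(f"exactly two of ALK/DIC/pH/pCO2 required, got {sorted(given)}")

    if pH is not None and DIC is not None:
        ALK = alk_from_ph_dic(pH, DIC, c)
    elif pH is not None and pCO2 is not None:
        DIC = dic_from_ph_pco2(pH, pCO2, c)
        ALK = alk_from_ph_dic(pH, DIC, c)
    elif pH is not None and ALK is not None:
        DIC = dic_from_ph_alk(pH, ALK, c)
    elif ALK is not None and DIC is not None:
        pH = pH_from_alk_dic(ALK, DIC, c)
    elif ALK is not None and pCO2 is not None:
        # one-dimensional root in pH: DIC(pH, pCO2) must also satisfy ALK
        def residual(ph: float) -> float:
            return alk_from_ph_dic(ph, dic_from_ph_pco2(ph, pCO2, c), c) - ALK

        lo, hi = _PH_BRACKET
        if residual(lo) * residual(hi) > 0:
            raise NoSolutionError(f"no pH root for ALK={ALK}, pCO2={pCO2}")
        pH = float(brentq(residual, lo, hi, xtol=_PH_XTOL))
        DIC = dic_from_ph_pco2(pH, pCO2, c)
    else:
        raise InvalidInputError("the (DIC, pCO2) pair is not supported")

    if pCO2 is None:
        pCO2 = pco2_from_ph_dic(pH, DIC, c)
    return SeawaterState(T=float(T), S=float(S), ALK=float(ALK), DIC=float(DIC),
                         pH=float(pH), pCO2=float(pCO2))


def alk_change_for_ph_step(
    ph_start: float,
    ph_end: float,
    T: float,
    S: float,
    DIC: float | None = None,
    pCO2: float | None = None,
) -> float:
    """Alkalinity increase (umol/kg) needed for a pH step, at fixed DIC or fixed pCO2.

    The two formulations answer different scenario questions (a closed parcel
    vs. one equilibrating with the atmosphere) and give different numbers;
    both are exposed and neither is privileged.
    """
    if (DIC is None) == (pCO2 is None):
        raise InvalidInputError("give exactly one of DIC or pCO2")
    kwargs = {"DIC": DIC} if DIC is not None else {"pCO2": pCO2}
    a0 = solve_state(T, S, pH=ph_start, **kwargs).ALK
    a1 = solve_state(T, S, pH=ph_end, **kwargs).ALK
    return float(a1 - a0)
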
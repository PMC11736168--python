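"""Sclerochronology: calendar years from seasonal Mg/Ca cycles.

Coralline algae deposit one Mg/Ca cycle per year (warm-season maxima), and a
specimen collected alive has its uppermost surface at the collection year.
Annual anchors are the local maxima of the smoothed, linearly detrended Mg/Ca
transect; years are counted backwards from the collection year, and milled
bands are dated by which annual interval they overlap most.

Defaults follow a dominant-frequency heuristic: the smoothing window is 1/8
of the median cycle length estimated from the periodogram, and the peak
prominence threshold is 0.25 x the interquartile range of the detrended
series.  All steps are deterministic and invariant to a uniform rescaling of
the distance axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .exceptions import InsufficientSignalError, InvalidInputError

__all__ = ["AgeModel", "count_cycles", "assign_years"]


@dataclass(frozen=True)
class AgeModel:
    """Piecewise-constant map from distance below the growth surface to year.

    ``boundaries`` holds (start_distance_um, year_ce) for each annual
    interval, youngest first; an interval extends to the next start (the
    last one to infinity).  The partial outermost year is assigned to the
    collection year.
    """

    boundaries: tuple[tuple[float, int], ...]
    collection_year: int

    def __post_init__(self):
        years = [y for _, y in self.boundaries]
        if years and (years[0] != self.collection_year or np.any(np.diff(years) != -1)):
            raise InvalidInputError("years must decrease by 1 from the collection year")

    @property
    def n_years(self) -> int:
        return len(self.boundaries)

    @property
    def span(self) -> tuple[int, int]:
        """(oldest, youngest) calendar year covered."""
        return self.boundaries[-1][1], self.boundaries[0][1]

    def interval(self, i: int) -> tuple[float, float]:
        start = self.boundaries[i][0]
        end = self.boundaries[i + 1][0] if i + 1 < len(self.boundaries) else np.inf
        return start, end

    def year_at(self, distance_um: float) -> int | None:
        """Year containing a point distance, or None when above the surface."""
        if distance_um < 0:
            return None
        for i in range(self.n_years):
            start, end = self.interval(i)
            if start <= distance_um < end:
                return self.boundaries[i][1]
        return None


def _median_cycle_length(x: np.ndarray, dx: float) -> float:
    freqs, power = signal.periodogram(x, fs=1.0 / dx, detrend=False)
    if len(freqs) < 2 or not np.any(power[1:] > 0):
        raise InsufficientSignalError("no spectral power in transect")
    f_dom = freqs[1:][np.argmax(power[1:])]
    if f_dom <= 0:
        raise InsufficientSignalError("no dominant cycle found in transect")
    return 1.0 / f_dom


def count_cycles(
    transect: pd.DataFrame,
    collection_year: int,
    smoothing_window: float | None = None,
    min_prominence: float | None = None,
) -> AgeModel:
    """Build an age model by counting seasonal Mg/Ca maxima.

    Parameters
    ----------
    transect
        Columns ``distance_um`` (strictly increasing, from the growth
        surface inward) and ``MgCa_mmolmol``.
    collection_year
        Calendar year the living surface corresponds to.
    smoothing_window, min_prominence
        Moving-mean window (um) and peak prominence (mmol/mol); by default
        derived from the data (see module docstring).
    """
    d = transect["distance_um"].to_numpy(dtype=float)
    mg = transect["MgCa_mmolmol"].to_numpy(dtype=float)
    if len(d) < 6:
        raise InsufficientSignalError("transect too short")
    if np.any(np.diff(d) <= 0) or d[0] < 0:
        raise InvalidInputError("distances must be non-negative and strictly increasing")

    # resample to a uniform grid so peak prominence and smoothing are in
    # consistent units even for unevenly spaced laser transects
    dx = float(np.median(np.diff(d)))
    grid = np.arange(d[0], d[-1] + dx / 2, dx)
    mg_u = np.interp(grid, d, mg)
    detr = signal.detrend(mg_u, type="linear")

    cycle_len = _median_cycle_length(detr, dx)
    if smoothing_window is None:
        smoothing_window = cycle_len / 8.0
    win = max(1, int(round(smoothing_window / dx)))
    smooth = pd.Series(detr).rolling(win, center=True, min_periods=1).mean().to_numpy()

    if min_prominence is None:
        q75, q25 = np.percentile(smooth, [75, 25])
        min_prominence = 0.25 * (q75 - q25)
    # reflect-pad by half a cycle so maxima truncated by the transect ends
    # keep their full prominence; edge samples themselves can then surface as
    # candidate peaks and are adjudicated by a length-consistency rule below
    pad = max(1, int(round(cycle_len / 2.0 / dx)))
    padded = np.pad(smooth, pad, mode="reflect")
    peaks, _ = signal.find_peaks(padded, prominence=min_prominence)
    peaks = peaks[(peaks >= pad) & (peaks < pad + len(smooth))] - pad
    last = len(smooth) - 1
    interior = peaks[(peaks > 0) & (peaks < last)]
    if len(interior) >= 2:
        # a candidate peak sitting exactly on an end sample is ambiguous: it
        # is either a genuine annual maximum at the boundary or the mirror of
        # an unsampled one.  Accept edge candidates (surface first) only when
        # the sampled length, in units of the median annual spacing, implies
        # more years than the interior maxima provide.
        spacing = float(np.median(np.diff(grid[interior])))
        n_expected = int(round((grid[-1] - grid[0] + dx) / spacing))
        deficit = n_expected - len(interior)
        accepted = list(interior)
        for edge in (0, last):
            if deficit > 0 and edge in peaks:
                accepted.append(edge)
                deficit -= 1
        peaks = np.sort(np.asarray(accepted, dtype=int))
    if len(peaks) < 2:
        raise InsufficientSignalError(f"only {len(peaks)} seasonal cycles detected; need >= 2")

    anchors = grid[peaks]  # youngest (nearest surface) first
    # annual interval boundaries midway between consecutive anchors; the
    # partial outermost interval [0, first midpoint) is the collection year
    midpoints = (anchors[:-1] + anchors[1:]) / 2.0
    starts = np.concatenate([[0.0], midpoints])
    boundaries = tuple(
        (float(s), collection_year - i) for i, s in enumerate(starts)
    )
    return AgeModel(boundaries=boundaries, collection_year=collection_year)


def assign_years(
    records: pd.DataFrame,
    age_model: AgeModel,
    band_width_um: float = 280.0,
) -> pd.DataFrame:
    """Date milled bands against an age model.

    Each band (centre ``distance_um``, extent ``band_width_um``) takes the
    year of the annual interval it overlaps most; a band straddling a
    boundary with equal overlap takes the younger year.  Bands outside the
    transect range get a missing year and a warning.
    """
    out = records.copy()
    years: list[float] = []
    for _, rec in out.iterrows():
        centre = float(rec["distance_um"])
        lo, hi = centre - band_width_um / 2.0, centre + band_width_um / 2.0
        best_year, best_overlap = None, -1.0
        for i in range(age_model.n_years):
            start, end = age_model.interval(i)
            overlap = min(hi, end) - max(lo, start)
            year = age_model.boundaries[i][1]
            # strict > keeps the first (younger) interval on exact ties
            if overlap > best_overlap and overlap > 0:
                best_year, best_overlap = year, overlap
        if best_year is None:
            warnings.warn(f"band at {centre} um outside the dated transect range", stacklevel=2)
            years.append(np.nan)
        else:
            years.append(best_year)
    out["year_ce"] = pd.array(years, dtype="Int64")
    return out
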
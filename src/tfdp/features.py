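"""Extraction of the two-peak (T1m, T2m) biomarker from derivative curves.

Tear-fluid denaturation profiles show two major apexes in the derivative of
the fluorescence ratio, near 65 degC (T1m, dominated by lysozyme,
lipocalin-1 and apo-lactotransferrin) and near 78 degC (T2m, dominated by
serum albumin and immunoglobulin A).  The pair of apex temperatures is the
compact biomarker used for clustering; this module locates the apexes by
prominence-filtered local-maximum detection with quadratic refinement, and
handles apexes censored at the scan boundary (e.g. Fe3+-loaded
lactotransferrin melting at the 95 degC scan limit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import InvalidInputError
from .io import DEFAULT_GRID, NanoDSFRun, SixCurveSet, TemperatureGrid, six_curves

__all__ = ["PeakPair", "PeakSettings", "detect_peaks", "extract_cohort"]


@dataclass(frozen=True)
class PeakSettings:
    """Detection settings: prominence floor (fraction of the derivative span),
    the temperature splitting T1m-like from T2m-like single peaks, and the
    smoothing used when curves must be built from raw runs."""

    min_prominence_frac: float = 0.05
    split_temp: float = 71.0
    smoothing_window_c: float = 5.0
    polyorder: int = 3


@dataclass(frozen=True)
class PeakPair:
    """The (T1m, T2m) biomarker of one profile.

    Either temperature may be absent (``None``) when the profile shows fewer
    than two qualifying peaks.  ``censored1``/``censored2`` flag apexes that
    coincide with a grid edge (true apex outside the scan range).
    ``n_raw_peaks`` counts qualifying candidates before the two-most-prominent
    selection.
    """

    t1m: float | None = None
    t2m: float | None = None
    prominence1: float = 0.0
    prominence2: float = 0.0
    censored1: bool = False
    censored2: bool = False
    n_raw_peaks: int = 0

    def __post_init__(self) -> None:
        if self.t1m is not None and self.t2m is not None and not self.t1m < self.t2m:
            raise InvalidInputError("t1m must be < t2m when both peaks are present")
        if self.prominence1 < 0 or self.prominence2 < 0:
            raise InvalidInputError("prominences must be >= 0")

    @property
    def complete(self) -> bool:
        return self.t1m is not None and self.t2m is not None


def _refine_apex(temps: np.ndarray, d: np.ndarray, i: int, step: float) -> float:
    """3-point quadratic interpolation of an interior apex position."""
    if i == 0 or i == len(d) - 1:
        return float(temps[i])
    denom = d[i - 1] - 2.0 * d[i] + d[i + 1]
    if denom >= 0 or not np.isfinite(denom):
        return float(temps[i])
    offset = 0.5 * (d[i - 1] - d[i + 1]) / denom
    offset = float(np.clip(offset, -0.5, 0.5))
    return float(temps[i] + offset * step)


def _boundary_candidate(d: np.ndarray, edge: str, min_run: int) -> tuple[int, float] | None:
    """A monotone run ending at a grid edge makes the edge a censored candidate.

    The run must span at least ``min_run`` points so that single-point noise
    excursions at the (one-sided-fitted, noisier) curve ends do not qualify.
    Returns (edge index, prominence of the run) or None.
    """
    n = len(d)
    if edge == "right":
        i = n - 1
        while i > 0 and d[i - 1] <= d[i]:
            i -= 1
        if n - 1 - i >= min_run and d[n - 1] > d[i]:
            return n - 1, float(d[n - 1] - d[i])
    else:
        i = 0
        while i < n - 1 and d[i + 1] <= d[i]:
            i += 1
        if i >= min_run and d[0] > d[i]:
            return 0, float(d[0] - d[i])
    return None


def detect_peaks(
    curves: SixCurveSet,
    min_prominence_frac: float = 0.05,
    split_temp: float = 71.0,
    min_boundary_run_c: float = 1.5,
) -> PeakPair:
    """Locate the (T1m, T2m) apex pair on the d(F350/F330)/dT curve.

    Local maxima with prominence >= ``min_prominence_frac`` x (span of the
    derivative curve) are candidates; a monotone run terminating at a grid
    edge contributes a boundary candidate at the edge temperature, flagged as
    censored; the run must extend >= ``min_boundary_run_c`` degC so that a
    noise excursion on the last few (one-sided-fitted, noisier) points does
    not qualify.  When more than two candidates qualify, the two most prominent
    are kept; a lone peak is assigned to T2m when its apex is at or above
    ``split_temp`` and to T1m otherwise.  Interior apexes are refined by
    3-point quadratic interpolation and reported to 0.1 degC.

    A featureless (flat) curve yields an empty :class:`PeakPair`, not an error.
    """
    if not 0.0 < min_prominence_frac < 1.0:
        raise InvalidInputError("min_prominence_frac must be in (0, 1)")
    d = np.asarray(curves.d_ratio, dtype=float)
    temps = curves.grid.values
    span = float(d.max() - d.min())
    if not np.isfinite(span) or span <= 0.0:
        return PeakPair(n_raw_peaks=0)
    threshold = min_prominence_frac * span

    interior_idx, props = find_peaks(d, prominence=threshold)
    candidates: list[tuple[float, float, bool]] = [
        (_refine_apex(temps, d, int(i), curves.grid.step), float(p), False)
        for i, p in zip(interior_idx, props["prominences"])
    ]
    min_run = max(2, int(round(min_boundary_run_c / curves.grid.step)))
    for edge in ("left", "right"):
        hit = _boundary_candidate(d, edge, min_run)
        if hit is not None and hit[1] >= threshold:
            candidates.append((float(temps[hit[0]]), hit[1], True))

    n_raw = len(candidates)
    if n_raw == 0:
        return PeakPair(n_raw_peaks=0)
    if n_raw > 2:
        candidates = sorted(candidates, key=lambda c: c[1], reverse=True)[:2]
    candidates.sort(key=lambda c: c[0])

    if len(candidates) == 1:
        t, prom, cens = candidates[0]
        t = round(t, 1)
        if t >= split_temp:
            return PeakPair(t2m=t, prominence2=prom, censored2=cens, n_raw_peaks=n_raw)
        return PeakPair(t1m=t, prominence1=prom, censored1=cens, n_raw_peaks=n_raw)

    (ta, pa, ca), (tb, pb, cb) = candidates
    if round(ta, 1) == round(tb, 1):  # merged after rounding: report once
        t, prom, cens = max(candidates, key=lambda c: c[1])
        t = round(t, 1)
        if t >= split_temp:
            return PeakPair(t2m=t, prominence2=prom, censored2=cens, n_raw_peaks=n_raw)
        return PeakPair(t1m=t, prominence1=prom, censored1=cens, n_raw_peaks=n_raw)
    return PeakPair(
        t1m=round(ta, 1),
        t2m=round(tb, 1),
        prominence1=pa,
        prominence2=pb,
        censored1=ca,
        censored2=cb,
        n_raw_peaks=n_raw,
    )


def extract_cohort(
    runs: list[NanoDSFRun],
    grid: TemperatureGrid = DEFAULT_GRID,
    settings: PeakSettings = PeakSettings(),
) -> pd.DataFrame:
    """Extract one (T1m, T2m) row per run.

    Returns a table with columns ``sample_id, label, t1m, t2m, prominence1,
    prominence2, censored1, censored2, complete``; rows with a missing peak
    have ``complete = False`` and are excluded from clustering by default.
    Duplicate sample ids are an error.
    """
    ids = [r.sample_id for r in runs]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise InvalidInputError(f"duplicate sample_id(s): {sorted(dupes)}")
    rows = []
    for run in runs:
        curves = six_curves(
            run, grid, smoothing_window_c=settings.smoothing_window_c, polyorder=settings.polyorder
        )
        pk = detect_peaks(
            curves,
            min_prominence_frac=settings.min_prominence_frac,
            split_temp=settings.split_temp,
        )
        rows.append(
            {
                "sample_id": run.sample_id,
                "label": run.label,
                "t1m": pk.t1m,
                "t2m": pk.t2m,
                "prominence1": pk.prominence1,
                "prominence2": pk.prominence2,
                "censored1": pk.censored1,
                "censored2": pk.censored2,
                "complete": pk.complete,
            }
        )
    columns = [
        "sample_id", "label", "t1m", "t2m",
        "prominence1", "prominence2", "censored1", "censored2", "complete",
    ]
    return pd.DataFrame(rows, columns=columns)
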
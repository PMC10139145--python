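"""Data model and I/O for nanoDSF melting scans.

A melting scan records intrinsic fluorescence of a protein sample at 330 and
350 nm while the temperature is ramped (here 35-95 degC by default).  The
denaturation profile used downstream is the six-curve set: F330, F350, their
ratio F350/F330, and the first temperature derivatives of all three.

This module holds the in-memory containers (:class:`NanoDSFRun`,
:class:`SixCurveSet`, :class:`TemperatureGrid`), long/wide CSV readers and the
long-format writer, cubic-spline resampling onto a common grid, and
Savitzky-Golay smoothing-differentiation to build the six curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import InterpolatedUnivariateSpline
from scipy.signal import savgol_filter

from .errors import ConfigurationError, GridRangeError, InvalidInputError, ParseError

__all__ = [
    "TemperatureGrid",
    "NanoDSFRun",
    "SixCurveSet",
    "read_runs",
    "write_runs",
    "resample",
    "six_curves",
    "DEFAULT_GRID",
]

_MIN_RUN_LENGTH = 16
_LONG_COLUMNS = ("sample_id", "temperature", "f330", "f350")


@dataclass(frozen=True)
class TemperatureGrid:
    """A uniform temperature grid in degC.

    Defaults cover the instrument's standard 35-95 degC ramp at 0.1 degC
    resolution (601 points).
    """

    start: float = 35.0
    stop: float = 95.0
    step: float = 0.1

    def __post_init__(self) -> None:
        if not (np.isfinite(self.start) and np.isfinite(self.stop) and np.isfinite(self.step)):
            raise InvalidInputError("grid bounds and step must be finite")
        if self.step <= 0 or self.stop <= self.start:
            raise InvalidInputError(
                f"grid must be strictly increasing: start={self.start}, stop={self.stop}, step={self.step}"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    @property
    def values(self) -> np.ndarray:
        return np.linspace(self.start, self.stop, self.n_points)


DEFAULT_GRID = TemperatureGrid()


def _as_series(name: str, values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise InvalidInputError(f"{name} must be one-dimensional")
    return arr


@dataclass
class NanoDSFRun:
    """One melting scan: a temperature series plus the two fluorescence channels.

    Parameters
    ----------
    sample_id:
        Unique identifier of the capillary/subject.
    temperatures:
        Strictly increasing temperatures in degC.
    f330, f350:
        Fluorescence intensity (RFU) at 330 and 350 nm; strictly positive.
    label:
        Optional class label (e.g. ``"CONTROL"`` or ``"POAG"``).
    meta:
        Free-form subject metadata (age, gender, treatments ...).
    """

    sample_id: str
    temperatures: np.ndarray
    f330: np.ndarray
    f350: np.ndarray
    label: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temperatures = _as_series("temperatures", self.temperatures)
        self.f330 = _as_series("f330", self.f330)
        self.f350 = _as_series("f350", self.f350)
        n = len(self.temperatures)
        if not (len(self.f330) == len(self.f350) == n):
            raise InvalidInputError(f"run {self.sample_id!r}: series lengths differ")
        if n < _MIN_RUN_LENGTH:
            raise InvalidInputError(
                f"run {self.sample_id!r}: needs >= {_MIN_RUN_LENGTH} points, got {n}"
            )
        if not np.all(np.diff(self.temperatures) > 0):
            raise InvalidInputError(f"run {self.sample_id!r}: temperatures not strictly increasing")
        for name, y in (("f330", self.f330), ("f350", self.f350)):
            if not np.all(np.isfinite(y)) or np.any(y <= 0):
                raise InvalidInputError(f"run {self.sample_id!r}: {name} must be finite and > 0")

    def __len__(self) -> int:
        return len(self.temperatures)

    @property
    def ratio(self) -> np.ndarray:
        """Pointwise F350/F330."""
        return self.f350 / self.f330


@dataclass
class SixCurveSet:
    """The six-curve denaturation profile on a common grid.

    ``ratio`` is the pointwise F350/F330 of the (resampled, unsmoothed)
    channels; the three ``d_*`` series are smoothed first derivatives with
    respect to temperature (units: RFU/degC resp. 1/degC).
    """

    grid: TemperatureGrid
    f330: np.ndarray
    f350: np.ndarray
    ratio: np.ndarray
    d_f330: np.ndarray
    d_f350: np.ndarray
    d_ratio: np.ndarray

    def __post_init__(self) -> None:
        n = self.grid.n_points
        for name in ("f330", "f350", "ratio", "d_f330", "d_f350", "d_ratio"):
            if len(getattr(self, name)) != n:
                raise InvalidInputError(f"{name} length does not match grid ({n})")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "temperature": self.grid.values,
                "f330": self.f330,
                "f350": self.f350,
                "ratio": self.ratio,
                "d_f330": self.d_f330,
                "d_f350": self.d_f350,
                "d_ratio": self.d_ratio,
            }
        )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_runs(path: str | Path, dialect: Literal["long", "wide"] = "long") -> list[NanoDSFRun]:
    """Read melting runs from a CSV file.

    Long format (canonical): columns ``sample_id, [label,] temperature, f330,
    f350``, one row per temperature point.  Wide format (read-only): one
    ``temperature`` column plus paired per-sample columns named
    ``<sample>_f330`` / ``<sample>_f350``.

    Returns runs sorted by ``sample_id``; per-run invariants are enforced and
    violations raise :class:`ParseError` naming the sample and row.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    df = pd.read_csv(path)
    if dialect == "long":
        return _runs_from_long(df, source=str(path))
    if dialect == "wide":
        return _runs_from_wide(df, source=str(path))
    raise InvalidInputError(f"unknown dialect {dialect!r}")


def _runs_from_long(df: pd.DataFrame, source: str) -> list[NanoDSFRun]:
    missing = [c for c in _LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{source}: missing required column(s) {missing}")
    has_label = "label" in df.columns
    runs: list[NanoDSFRun] = []
    for sample_id, grp in df.groupby("sample_id", sort=True):
        grp = grp.reset_index()
        temps = grp["temperature"].to_numpy(float)
        bad = np.flatnonzero(np.diff(temps) <= 0)
        if bad.size:
            row = int(grp["index"].iloc[bad[0] + 1]) + 2  # 1-based incl. header
            raise ParseError(
                f"{source}: sample {sample_id!r}: temperatures not strictly increasing at row {row}"
            )
        for chan in ("f330", "f350"):
            vals = grp[chan].to_numpy(float)
            bad = np.flatnonzero(~np.isfinite(vals) | (vals <= 0))
            if bad.size:
                row = int(grp["index"].iloc[bad[0]]) + 2
                raise ParseError(
                    f"{source}: sample {sample_id!r}: non-positive/non-finite {chan} at row {row}"
                )
        label = None
        if has_label:
            lab = grp["label"].iloc[0]
            label = None if pd.isna(lab) else str(lab)
        try:
            runs.append(
                NanoDSFRun(str(sample_id), temps, grp["f330"].to_numpy(float), grp["f350"].to_numpy(float), label=label)
            )
        except InvalidInputError as exc:
            raise ParseError(f"{source}: {exc}") from exc
    return runs


def _runs_from_wide(df: pd.DataFrame, source: str) -> list[NanoDSFRun]:
    if "temperature" not in df.columns:
        raise ParseError(f"{source}: wide dialect requires a 'temperature' column")
    temps = df["temperature"].to_numpy(float)
    ids_330 = {c[: -len("_f330")] for c in df.columns if c.endswith("_f330")}
    ids_350 = {c[: -len("_f350")] for c in df.columns if c.endswith("_f350")}
    if ids_330 != ids_350:
        raise ParseError(f"{source}: unpaired channel columns for sample(s) {sorted(ids_330 ^ ids_350)}")
    if not ids_330:
        raise ParseError(f"{source}: no '<sample>_f330'/'<sample>_f350' column pairs found")
    runs = []
    for sid in sorted(ids_330):
        try:
            runs.append(
                NanoDSFRun(sid, temps, df[f"{sid}_f330"].to_numpy(float), df[f"{sid}_f350"].to_numpy(float))
            )
        except InvalidInputError as exc:
            raise ParseError(f"{source}: {exc}") from exc
    return runs


def write_runs(runs: Iterable[NanoDSFRun], path: str | Path) -> Path:
    """Write runs as the canonical long CSV (6 significant digits)."""
    frames = []
    for run in runs:
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": run.sample_id,
                    "label": run.label if run.label is not None else "",
                    "temperature": run.temperatures,
                    "f330": run.f330,
                    "f350": run.f350,
                }
            )
        )
    path = Path(path)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6g")
    return path


# ---------------------------------------------------------------------------
# Resampling and the six-curve construction
# ---------------------------------------------------------------------------

def resample(run: NanoDSFRun, grid: TemperatureGrid = DEFAULT_GRID) -> NanoDSFRun:
    """Interpolate both channels onto ``grid`` with an interpolating cubic spline.

    The spline is exact at the original knots; extrapolation is refused.
    """
    t = run.temperatures
    g = grid.values
    eps = 1e-9
    if g[0] < t[0] - eps or g[-1] > t[-1] + eps:
        raise GridRangeError(
            f"run {run.sample_id!r}: grid [{g[0]}, {g[-1]}] exceeds data span [{t[0]}, {t[-1]}]"
        )
    g = np.clip(g, t[0], t[-1])
    f330 = InterpolatedUnivariateSpline(t, run.f330, k=3)(g)
    f350 = InterpolatedUnivariateSpline(t, run.f350, k=3)(g)
    return replace(run, temperatures=grid.values.copy(), f330=f330, f350=f350)


def _on_grid(run: NanoDSFRun, grid: TemperatureGrid) -> bool:
    return len(run) == grid.n_points and np.allclose(run.temperatures, grid.values, atol=1e-9)


def six_curves(
    run: NanoDSFRun,
    grid: TemperatureGrid = DEFAULT_GRID,
    smoothing_window_c: float = 5.0,
    polyorder: int = 3,
) -> SixCurveSet:
    """Build the six-curve profile of a run on a common grid.

    The run is spline-resampled onto ``grid`` (no-op when already aligned),
    the ratio is formed from the raw resampled channels, and the three
    derivatives are obtained by Savitzky-Golay smoothing-differentiation with
    the given window (degC) and polynomial order.  Points in the half-window
    at each grid end are fitted with one-sided polynomials (``mode="interp"``),
    so boundary peaks remain detectable.
    """
    window_pts = int(round(smoothing_window_c / grid.step))
    if window_pts % 2 == 0:
        window_pts += 1
    if window_pts < 3:
        raise ConfigurationError(
            f"smoothing window {smoothing_window_c} degC is shorter than 3 grid steps of {grid.step} degC"
        )
    if window_pts <= polyorder:
        raise ConfigurationError(
            f"smoothing window of {window_pts} points must exceed polyorder {polyorder}"
        )
    if not _on_grid(run, grid):
        run = resample(run, grid)
    ratio = run.f350 / run.f330

    def deriv(y: np.ndarray) -> np.ndarray:
        return savgol_filter(y, window_pts, polyorder, deriv=1, delta=grid.step, mode="interp")

    return SixCurveSet(
        grid=grid,
        f330=run.f330.copy(),
        f350=run.f350.copy(),
        ratio=ratio,
        d_f330=deriv(run.f330),
        d_f350=deriv(run.f350),
        d_ratio=deriv(ratio),
    )
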
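"""Per-cell and per-population statistics for mother-machine track data.

The central quantity is the growth-corrected *promoter activity*

    (1/A) d(I*A)/dt  =  I * (1/A)(dA/dt) + dI/dt,

where ``I`` is the mean fluorescence of a cell and ``A`` its area; the
relative area growth rate is taken as the instantaneous elongation rate
(log-difference of cell length between consecutive frames).  Activity
separates true transcriptional regulation from the passive concentration
changes caused by growth-rate shifts: a constitutive promoter shows a level
pulse during stress-induced growth arrest but constant activity.

Conventions (fixed here because they differ between toolkits):

* percentiles use numpy's linear interpolation between order statistics;
* the coefficient of variation uses the sample (n-1) standard deviation;
* a window ``(a, b)`` includes frames with ``a <= t <= b``; the treatment
  start frame t = 0 belongs to the basal window;
* the frame following a division (length drop below ``DIVISION_RATIO`` of
  the previous frame) yields no elongation/expression rate (NaN) -- the rate
  is undefined across the split;
* "relative to basal" means division by the pre-treatment (t <= 0) mean of
  frontier cells of the same gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "AnalysisWindows",
    "CellTrace",
    "elongation_rate",
    "expression_rate",
    "promoter_activity",
    "trace_peak",
    "trace_steady",
    "per_cell_window_means",
    "population_peak",
    "population_steady",
    "cell_time_to_peak",
    "cell_peak",
    "coefficient_of_variation",
    "gene_to_gene_cv",
    "relative_spatial_profile",
    "cross_correlation",
    "add_activity_columns",
]

DIVISION_RATIO = 0.75  # length ratio below which a frame is called a division


@dataclass(frozen=True)
class AnalysisWindows:
    """Time windows (minutes, relative to treatment start at t = 0).

    ``None`` as a bound means "start of the recording" / "end of the
    recording" respectively.
    """

    peak_level: tuple[float, float] = (12.0, 90.0)
    steady_level: tuple[float, float | None] = (150.0, None)
    peak_activity: tuple[float, float] = (9.0, 60.0)
    steady_activity: tuple[float, float] = (120.0, 180.0)
    basal: tuple[float | None, float] = (None, 0.0)
    single_cell_peak: tuple[float, float] = (18.0, 90.0)
    time_to_peak_horizon: float = 100.0

    def __post_init__(self) -> None:
        for name in ("peak_level", "steady_level", "peak_activity",
                     "steady_activity", "basal", "single_cell_peak"):
            a, b = getattr(self, name)
            if a is not None and b is not None and a >= b:
                raise DataError(f"window {name!r}: start {a} must be < end {b}")
        if self.time_to_peak_horizon <= 0:
            raise DataError("time_to_peak_horizon must be > 0")

    def mask(self, times: np.ndarray, window: tuple) -> np.ndarray:
        a, b = window
        m = np.ones(len(times), dtype=bool)
        if a is not None:
            m &= times >= a
        if b is not None:
            m &= times <= b
        return m


@dataclass
class CellTrace:
    """One cell's contiguous frames: geometry, fluorescence, position."""

    times: np.ndarray
    lengths: np.ndarray
    areas: np.ndarray
    intensities: np.ndarray
    barrier_count: np.ndarray | None = None
    cell_id: int | None = None
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, cell_id=None) -> "CellTrace":
        df = df.sort_values("time_min")
        return cls(
            times=df["time_min"].to_numpy(float),
            lengths=df["length_um"].to_numpy(float),
            areas=df["area_um2"].to_numpy(float),
            intensities=df["intensity"].to_numpy(float),
            barrier_count=df["barrier_count"].to_numpy()
            if "barrier_count" in df else None,
            cell_id=cell_id,
        )


# -- per-frame rates --------------------------------------------------------

def elongation_rate(times: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Instantaneous elongation rate: (log L_t - log L_{t-dt}) / dt.

    Returns one value per frame; the first frame and any division frame
    (length drop) are NaN.  Raises on non-positive lengths.
    """
    times = np.asarray(times, float)
    lengths = np.asarray(lengths, float)
    if len(times) < 2:
        raise DataError("elongation_rate needs at least 2 frames")
    if np.any(lengths <= 0):
        raise DataError("cell lengths must be > 0")
    dt = np.diff(times)
    rate = np.diff(np.log(lengths)) / dt
    ratio = lengths[1:] / lengths[:-1]
    rate[ratio < DIVISION_RATIO] = np.nan
    return np.concatenate([[np.nan], rate])


def expression_rate(times: np.ndarray, intensities: np.ndarray) -> np.ndarray:
    """Instantaneous expression rate: (I_t - I_{t-dt}) / dt (first frame NaN)."""
    times = np.asarray(times, float)
    intensities = np.asarray(intensities, float)
    if len(times) < 2:
        raise DataError("expression_rate needs at least 2 frames")
    return np.concatenate([[np.nan], np.diff(intensities) / np.diff(times)])


def promoter_activity(times, lengths, intensities) -> np.ndarray:
    """Growth-corrected production rate: I * elongation_rate + expression_rate."""
    return (
        np.asarray(intensities, float) * elongation_rate(times, lengths)
        + expression_rate(times, intensities)
    )


# -- single-trace summaries -------------------------------------------------

def _window_values(times, values, window, name: str) -> np.ndarray:
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    a, b = window
    m = np.ones(len(times), bool)
    if a is not None:
        m &= times >= a
    if b is not None:
        m &= times <= b
    m &= ~np.isnan(values)
    if not m.any():
        raise DataError(f"no frames inside window {name!r} = {window}")
    return values[m]

def trace_peak(times, values, window=(12.0, 90.0)) -> float:
    """90th percentile (linear interpolation) of the values inside ``window``."""
    return float(np.percentile(_window_values(times, values, window, "peak"), 90))


def trace_steady(times, values, window=(150.0, None)) -> float:
    """Mean of the values inside ``window``."""
    return float(np.mean(_window_values(times, values, window, "steady")))


def cell_time_to_peak(times, intensities, windows: AnalysisWindows | None = None) -> float:
    """Time (min post treatment) of a cell's maximum intensity within the horizon.

    Frames with 0 < t <= horizon are considered; ties break to the earliest
    frame.
    """
    windows = windows or AnalysisWindows()
    times = np.asarray(times, float)
    intensities = np.asarray(intensities, float)
    m = (times > 0) & (times <= windows.time_to_peak_horizon) & ~np.isnan(intensities)
    if not m.any():
        raise DataError("no frames inside the time-to-peak horizon")
    t_win, v_win = times[m], intensities[m]
    return float(t_win[np.argmax(v_win)])


def cell_peak(times, intensities, windows: AnalysisWindows | None = None) -> float:
    """Mean intensity in the single-cell peak window minus the basal mean."""
    windows = windows or AnalysisWindows()
    peak = np.mean(_window_values(times, intensities, windows.single_cell_peak,
                                  "single_cell_peak"))
    basal = np.mean(_window_values(times, intensities, windows.basal, "basal"))
    return float(peak - basal)


# -- population summaries on track tables -----------------------------------

def add_activity_columns(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorised per-cell rates for a track table (long format).

    Adds ``elongation_rate``, ``expression_rate`` and ``activity`` columns,
    computed within each (gene, channel, cell_id) trace; first frames and
    division frames are NaN.
    """
    keys = [k for k in ("gene", "channel", "cell_id") if k in records.columns]
    df = records.sort_values(keys + ["time_min"]).reset_index(drop=True)
    grp = df.groupby(keys, sort=False)
    same_cell = ~grp.cumcount().eq(0).to_numpy()
    dt = df["time_min"].diff().to_numpy(float)
    l_ratio = (df["length_um"] / df["length_um"].shift()).to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        elong = np.log(l_ratio) / dt
        exprr = df["intensity"].diff().to_numpy(float) / dt
    elong[~same_cell | (l_ratio < DIVISION_RATIO)] = np.nan
    exprr[~same_cell] = np.nan
    df["elongation_rate"] = elong
    df["expression_rate"] = exprr
    df["activity"] = df["intensity"].to_numpy(float) * elong + exprr
    return df


def per_cell_window_means(
    records: pd.DataFrame,
    column: str,
    window: tuple,
    min_frames: int = 5,
    frontier_only: bool = True,
) -> pd.Series:
    """Per-cell mean of ``column`` over the frames inside ``window``.

    Cells contribute one value each (the Mann-Whitney unit downstream);
    cells with fewer than ``min_frames`` valid in-window frames are dropped.
    """
    df = records
    if frontier_only and "barrier_count" in df.columns:
        df = df[df["barrier_count"] == 0]
    a, b = window
    m = df[column].notna()
    if a is not None:
        m &= df["time_min"] >= a
    if b is not None:
        m &= df["time_min"] <= b
    df = df[m]
    if df.empty:
        raise DataError(f"no frames inside window {window} for column {column!r}")
    grp = df.groupby("cell_id")[column]
    means = grp.mean()
    counts = grp.count()
    return means[counts >= min_frames]


def population_peak(
    records: pd.DataFrame,
    windows: AnalysisWindows | None = None,
    column: str = "intensity",
    normalize_basal: bool = False,
) -> float:
    """Population peak expression: 90th percentile of per-cell mean
    intensities of frontier cells pooled over the peak window (12-90 min)."""
    windows = windows or AnalysisWindows()
    vals = per_cell_window_means(records, column, windows.peak_level)
    peak = float(np.percentile(vals.to_numpy(), 90))
    if normalize_basal:
        peak /= _basal_mean(records, windows, column)
    return peak


def population_steady(
    records: pd.DataFrame,
    windows: AnalysisWindows | None = None,
    column: str = "intensity",
    normalize_basal: bool = False,
) -> float:
    """Population steady-state expression: mean of per-cell mean intensities
    of frontier cells from 150 min onward."""
    windows = windows or AnalysisWindows()
    vals = per_cell_window_means(records, column, windows.steady_level)
    steady = float(vals.mean())
    if normalize_basal:
        steady /= _basal_mean(records, windows, column)
    return steady


def _basal_mean(records, windows: AnalysisWindows, column: str) -> float:
    vals = per_cell_window_means(records, column, windows.basal)
    mean = float(vals.mean())
    if mean == 0:
        raise DataError("basal mean is zero; cannot normalise")
    return mean


# -- variability ------------------------------------------------------------

def coefficient_of_variation(values) -> float:
    """Sample standard deviation (ddof=1) divided by the mean."""
    values = np.asarray(values, float)
    if values.size < 2:
        raise DataError("coefficient_of_variation needs at least 2 values")
    mean = values.mean()
    if mean == 0:
        raise DataError("coefficient_of_variation undefined for zero mean")
    return float(values.std(ddof=1) / mean)


def gene_to_gene_cv(mean_traces: pd.DataFrame, basal_window=( None, 0.0)) -> pd.Series:
    """Per-frame CV across genes of basal-normalised mean expression.

    ``mean_traces``: one column per gene, indexed by time (min).  Each gene is
    first normalised to its own pre-treatment mean.
    """
    if mean_traces.shape[1] < 2:
        raise DataError("gene_to_gene_cv needs at least 2 genes")
    t = mean_traces.index.to_numpy(float)
    a, b = basal_window
    m = np.ones(len(t), bool)
    if a is not None:
        m &= t >= a
    if b is not None:
        m &= t <= b
    if not m.any():
        raise DataError("no frames in the basal window")
    normed = mean_traces / mean_traces.loc[m].mean(axis=0)
    return normed.std(axis=1, ddof=1) / normed.mean(axis=1)


# -- space ------------------------------------------------------------------

def relative_spatial_profile(
    records: pd.DataFrame,
    window: tuple = (12.0, 90.0),
    column: str = "intensity",
) -> pd.Series:
    """Expression relative to the frontier cell, per barrier count.

    At every (trench, frame) inside ``window`` the intensity of each cell
    with k >= 1 barrier cells is divided by the intensity of that trench's
    outermost cell (k = 0) at the same frame; ratios are then averaged over
    frames and trenches.  The frontier ratio is exactly 1.  Trench-frames
    without an outermost cell are skipped with a warning.
    """
    a, b = window
    m = records[column].notna()
    if a is not None:
        m &= records["time_min"] >= a
    if b is not None:
        m &= records["time_min"] <= b
    df = records[m]
    if df.empty:
        raise DataError(f"no frames inside window {window}")
    frontier = (
        df[df["barrier_count"] == 0]
        .set_index(["trench_id", "time_min"])[column]
    )
    if frontier.index.has_duplicates:
        frontier = frontier.groupby(level=[0, 1]).mean()
    idx = pd.MultiIndex.from_frame(df[["trench_id", "time_min"]])
    denom = frontier.reindex(idx).to_numpy()
    missing = np.isnan(denom)
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} records skipped: trench-frame lacks a frontier cell"
        )
    ratio = df[column].to_numpy() / denom
    out = (
        pd.DataFrame({"barrier_count": df["barrier_count"].to_numpy(), "ratio": ratio})
        .dropna()
        .groupby("barrier_count")["ratio"]
        .mean()
    )
    return out


# -- temporal correlation ---------------------------------------------------

def _detrend(x: np.ndarray, window_frames: int) -> np.ndarray:
    """Subtract a centred moving average (reflected edges)."""
    k = max(int(window_frames), 1)
    kernel = np.ones(k) / k
    pad = k // 2
    xp = np.pad(x, pad, mode="edge")
    trend = np.convolve(xp, kernel, mode="same")[pad : pad + len(x)]
    return x - trend


def cross_correlation(
    traces_a: Sequence[np.ndarray] | np.ndarray,
    traces_b: Sequence[np.ndarray] | np.ndarray,
    max_lag: int,
    frame_interval: float = 3.0,
    detrend_minutes: float = 30.0,
) -> pd.Series:
    """Trench-averaged temporal cross-correlation of two reporter traces.

    ``traces_a``/``traces_b`` are matched per-trench steady-state segments
    (equal length within a trench).  Each trace is detrended by subtracting a
    moving average (default 30 min) to isolate fluctuations from the slow
    induction trend, then the Pearson correlation of ``a_t`` with ``b_{t+lag}``
    is computed for lags in ``[-max_lag, max_lag]`` frames and averaged over
    trenches.  Index of the result is the lag in minutes.
    """
    if isinstance(traces_a, np.ndarray) and traces_a.ndim == 1:
        traces_a, traces_b = [traces_a], [traces_b]
    if len(traces_a) != len(traces_b):
        raise DataError("need one trace_b per trace_a")
    w = max(int(round(detrend_minutes / frame_interval)), 2)
    lags = np.arange(-max_lag, max_lag + 1)
    acc = np.zeros(lags.size)
    n_used = 0
    for xa, xb in zip(traces_a, traces_b):
        xa, xb = np.asarray(xa, float), np.asarray(xb, float)
        if len(xa) != len(xb):
            raise DataError("paired traces must have equal length")
        if len(xa) < 2 * max_lag + 2:
            raise DataError(
                f"steady-state segment too short: {len(xa)} frames < {2 * max_lag + 2}"
            )
        da, db = _detrend(xa, w), _detrend(xb, w)
        vals = np.empty(lags.size)
        for i, lag in enumerate(lags):
            if lag >= 0:
                x, y = da[: len(da) - lag], db[lag:]
            else:
                x, y = da[-lag:], db[: len(db) + lag]
            sx, sy = x.std(), y.std()
            vals[i] = np.nan if sx == 0 or sy == 0 else float(
                np.corrcoef(x, y)[0, 1]
            )
        acc += vals
        n_used += 1
    return pd.Series(acc / n_used, index=lags * frame_interval, name="cross_correlation")
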
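"""Seeded synthetic mother-machine track datasets.

Two generation modes share one cell-geometry engine:

* **planted** -- phenomenological promoter-activity templates with known
  ground truth.  Each gene category prescribes an activity profile (flat,
  sustained step, compact pulse ending by ~100 min, or their downregulated
  mirrors); expression *level* is the integral of activity minus dilution
  with a growth-arrest profile shared by every gene, so even "none" and
  "down" templates show the passive expression pulse that growth arrest
  produces in real data.
* **mechanistic** -- intensities are read off stress-model trajectories
  (per trench position, with the external dose attenuated per barrier cell),
  so spatial gradients and growth dynamics come from the ODE system.

Cells elongate exponentially at the (noisy) profile growth rate, divide at
roughly twice their birth length with 5% lognormal threshold noise and a
symmetric split, and occupy fixed trench positions: ``barrier_count`` 0 is
the frontier cell at the open end and the maximum is the mother cell at the
closed end.  The mother keeps its identity across divisions (it is
physically the same cell); at every other position a division hands the slot
to a daughter with a fresh cell id, so the table contains many short
frontier-cell tracks and one long mother track per trench.

Fluorescence per channel is (template or model trace) x slow Ornstein-
Uhlenbeck fluctuation x per-frame lognormal measurement noise.  Everything
is driven by one :func:`numpy.random.default_rng` seed; identical
configuration and seed reproduce the dataset bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import model as _model
from .errors import ConfigError, ParseError
from .metrics import trace_peak, trace_steady

__all__ = [
    "ChannelLayout",
    "NoiseModel",
    "ArrestProfile",
    "PlantedTemplate",
    "TrackDataset",
    "planted_trace",
    "generate_dataset",
    "generate_regulon",
    "write_tracks",
    "read_tracks",
    "regulon_panel_templates",
    "dose_panel_templates",
    "REGULON_CATEGORY_COUNTS",
]

CATEGORIES = ("sustained_up", "transient_up", "sustained_down", "transient_down", "none")
DYNAMICS = ("pulsatile", "gradual", "n/a")

_FINE_DT = 0.5          # min, internal integration grid for planted levels
_PULSE_SUPPORT = 100.0  # min, transient responses return to baseline by here
_RISE_TAU = 12.0        # min, induction rise time for sustained responses
_GROWTH_NOISE_SD = 0.05     # per-frame fractional elongation noise
_DIV_THRESHOLD_SD = 0.05    # lognormal sd of the division-length threshold
_BIRTH_LENGTH = 2.0         # um


@dataclass(frozen=True)
class ChannelLayout:
    """Geometry and timing of the recording.

    Frames run every ``frame_interval`` minutes from ``-t_pre`` (baseline)
    to ``+t_post`` (treatment), inclusive; treatment starts at t = 0.
    """

    n_trenches: int = 20
    cells_per_trench: int = 7
    frame_interval: float = 3.0
    t_pre: float = 120.0
    t_post: float = 360.0

    def __post_init__(self) -> None:
        if self.n_trenches < 1 or self.cells_per_trench < 1:
            raise ConfigError("layout counts must be >= 1")
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be > 0")

    @property
    def times(self) -> np.ndarray:
        n = int(round((self.t_pre + self.t_post) / self.frame_interval))
        return -self.t_pre + self.frame_interval * np.arange(n + 1)


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative noise on fluorescence.

    ``meas_cv``: per-frame lognormal measurement noise CV.  ``ou_cv`` and
    ``ou_tau``: stationary CV and correlation time (min) of the slow
    cell-intrinsic expression fluctuation; ``shared_fraction`` of its log
    variance is shared between the channels of one cell (for dual-reporter
    correlation studies).
    """

    meas_cv: float = 0.05
    ou_tau: float = 30.0
    ou_cv: float = 0.15
    shared_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.meas_cv < 0 or self.ou_cv < 0:
            raise ConfigError("noise CVs must be >= 0")
        if self.ou_tau <= 0:
            raise ConfigError("ou_tau must be > 0")
        if not (0.0 <= self.shared_fraction <= 1.0):
            raise ConfigError("shared_fraction must be in [0, 1]")

    @classmethod
    def off(cls) -> "NoiseModel":
        return cls(meas_cv=0.0, ou_cv=0.0)


@dataclass(frozen=True)
class ArrestProfile:
    """Shared growth-arrest time course for planted mode.

    g(t) = g_max for t <= 0 and g_max * (1 - depth * 2^(-t / half_time))
    afterwards: an immediate drop to ``(1-depth) * g_max`` recovering with the
    given half-time, mimicking the transient elongation arrest a sudden
    peroxide treatment causes.
    """

    g_max: float = 0.012
    depth: float = 0.9
    half_time: float = 30.0

    def __post_init__(self) -> None:
        if not (0 <= self.depth <= 1):
            raise ConfigError("arrest depth must be in [0, 1]")
        if self.g_max <= 0 or self.half_time <= 0:
            raise ConfigError("g_max and half_time must be > 0")

    def growth(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        g = np.full(t.shape, self.g_max)
        post = t > 0
        g[post] = self.g_max * (1.0 - self.depth * 2.0 ** (-t[post] / self.half_time))
        return g

    def _integral(self, t: np.ndarray) -> np.ndarray:
        """∫_0^t g dt' (closed form; negative t gives -g_max*|t|)."""
        t = np.asarray(t, float)
        pre = self.g_max * np.minimum(t, 0.0)
        tp = np.maximum(t, 0.0)
        h = self.half_time
        post = self.g_max * (tp - self.depth * h / np.log(2.0)
                             * (1.0 - 2.0 ** (-tp / h)))
        return pre + post

    def mean_growth(self, t: np.ndarray, dt: float) -> np.ndarray:
        """Average growth rate over [t, t+dt] -- what a discrete elongation
        rate over that frame interval measures."""
        return (self._integral(np.asarray(t, float) + dt) - self._integral(t)) / dt


@dataclass(frozen=True)
class PlantedTemplate:
    """Ground-truth specification of one gene's planted response.

    ``amplitude`` is the promoter-activity fold change at the category's
    defining feature: the *steady-state* activity for sustained categories
    (>1 up, <1 down) and the pulse extremum for transient categories; "none"
    ignores it.  ``peak_over_steady`` (sustained_up only) is the target ratio
    of measured expression-*level* peak (90th percentile, 12-90 min) to
    steady state (mean from 150 min); the generator calibrates an activity
    pulse so the noiseless trace hits it.  ``t_peak_mean``/``t_peak_sd``
    (min) give the distribution of single-cell intensity peak times; each
    cell's trace is time-shifted so its noiseless peak lands on its drawn
    value.
    """

    gene: str
    category: str
    dynamics: str = "n/a"
    peak_over_steady: float | None = None
    t_peak_mean: float = 25.0
    t_peak_sd: float = 5.0
    amplitude: float = 1.0
    basal: float = 200.0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ConfigError(f"unknown category {self.category!r}")
        if self.dynamics not in DYNAMICS:
            raise ConfigError(f"unknown dynamics {self.dynamics!r}")
        if self.dynamics != "n/a" and self.category != "sustained_up":
            raise ConfigError(
                "pulsatile/gradual dynamics apply only to sustained_up genes"
            )
        if self.category == "sustained_up" and self.peak_over_steady is None:
            raise ConfigError("sustained_up templates need peak_over_steady")
        if self.peak_over_steady is not None and self.peak_over_steady <= 0:
            raise ConfigError("peak_over_steady must be > 0")
        if self.basal <= 0:
            raise ConfigError("basal must be > 0")
        if self.category.endswith("_up") and self.amplitude <= 1.0 and self.category == "transient_up":
            raise ConfigError("transient_up amplitude must be > 1")
        if self.category.endswith("_down") and not (0 <= self.amplitude < 1):
            raise ConfigError("down-category amplitude must be in [0, 1)")
        if self.t_peak_sd < 0:
            raise ConfigError("t_peak_sd must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# -- planted activity / level construction ----------------------------------

_PULSE_CONC = 18.0  # beta-bump concentration; larger = narrower pulse


def _pulse_shape(t: np.ndarray, t_peak: float) -> np.ndarray:
    """Smooth compact bump on (0, 100) min with its mode at ``t_peak``, max 1."""
    u = np.clip(t / _PULSE_SUPPORT, 0.0, 1.0)
    a = _PULSE_CONC * t_peak / _PULSE_SUPPORT
    b = _PULSE_CONC - a
    mode = a / _PULSE_CONC
    peak_val = mode ** a * (1 - mode) ** b
    p = np.where((u > 0) & (u < 1), u ** a * (1 - u) ** b / peak_val, 0.0)
    return p


def _activity_multiplier(t: np.ndarray, tpl: PlantedTemplate, pulse_gain: float,
                         pulse_mode: float | None = None) -> np.ndarray:
    t = np.asarray(t, float)
    rise = np.where(t > 0, 1.0 - np.exp(-np.maximum(t, 0.0) / _RISE_TAU), 0.0)
    pulse = _pulse_shape(t, pulse_mode if pulse_mode is not None else tpl.t_peak_mean)
    if tpl.category == "sustained_up":
        m = 1.0 + (tpl.amplitude - 1.0) * rise + pulse_gain * pulse
    elif tpl.category == "transient_up":
        m = 1.0 + (tpl.amplitude - 1.0) * pulse
    elif tpl.category == "sustained_down":
        m = 1.0 - (1.0 - tpl.amplitude) * rise
    elif tpl.category == "transient_down":
        m = 1.0 - (1.0 - tpl.amplitude) * pulse
    else:  # none
        m = np.ones_like(t)
    return np.maximum(m, 0.0)


def _integrate_level(activity: np.ndarray, growth: np.ndarray, dt: float,
                     level0: float) -> np.ndarray:
    """Exponential-Euler integration of dI/dt = a(t) - g(t) I."""
    level = np.empty_like(activity)
    level[0] = level0
    decay = np.exp(-growth * dt)
    for k in range(1, len(activity)):
        g = max(growth[k - 1], 1e-12)
        level[k] = level[k - 1] * decay[k - 1] + activity[k - 1] * (1 - decay[k - 1]) / g
    return level


_TRACE_CACHE: dict = {}


class _TemplateTrace:
    """Noiseless fine-grid trace of one template.

    For sustained_up templates two quantities are calibrated jointly: the
    activity pulse *gain* so the measured level peak/steady ratio hits
    ``peak_over_steady``, and the pulse *position* so the noiseless level
    peaks at ``t_peak_mean`` (the published timing statistic is the
    single-cell intensity peak time, which lags the activity pulse).
    Instances are cached on (template, grid, arrest) since construction
    involves root finding.
    """

    def __init__(self, tpl: PlantedTemplate, t_pre: float, t_post: float,
                 arrest: ArrestProfile):
        self.template = tpl
        self.fine_times = np.arange(-t_pre, t_post + _FINE_DT / 2, _FINE_DT)
        self.growth = arrest.growth(self.fine_times)
        self.pulse_gain, self.pulse_mode = self._calibrate(tpl, arrest)
        act_mult = _activity_multiplier(self.fine_times, tpl, self.pulse_gain,
                                        self.pulse_mode)
        self.activity = tpl.basal * arrest.g_max * act_mult
        self.level = _integrate_level(self.activity, self.growth, _FINE_DT, tpl.basal)
        self.t_extremum = self._extremum_time()

    def _level_for(self, tpl, arrest, gain: float, mode: float) -> np.ndarray:
        act = tpl.basal * arrest.g_max * _activity_multiplier(
            self.fine_times, tpl, gain, mode)
        return _integrate_level(act, self.growth, _FINE_DT, tpl.basal)

    def _gain_for_ratio(self, tpl, arrest, mode: float) -> float:
        def ratio_err(gain: float) -> float:
            lvl = self._level_for(tpl, arrest, gain, mode)
            peak = trace_peak(self.fine_times, lvl, (12.0, 90.0))
            steady = trace_steady(self.fine_times, lvl, (150.0, None))
            return peak / steady - tpl.peak_over_steady

        lo, hi = 0.0, 2.0
        if ratio_err(lo) > 0:
            raise ConfigError(
                f"template {tpl.gene!r}: target peak_over_steady "
                f"{tpl.peak_over_steady} is below the pulse-free ratio"
            )
        while ratio_err(hi) < 0:
            hi *= 2
            if hi > 1e4:
                raise ConfigError(f"template {tpl.gene!r}: cannot reach target ratio")
        return brentq(ratio_err, lo, hi, xtol=1e-4, rtol=1e-4)

    def _calibrate(self, tpl: PlantedTemplate, arrest: ArrestProfile) -> tuple[float, float]:
        if tpl.category != "sustained_up":
            return 0.0, tpl.t_peak_mean
        # fixed-point iteration on the pulse position: the level peak lags the
        # activity pulse by a slowly varying amount, so shifting the pulse by
        # the current timing error converges in a few rounds.
        mode = tpl.t_peak_mean
        gain = self._gain_for_ratio(tpl, arrest, mode)
        for _ in range(12):
            lvl = self._level_for(tpl, arrest, gain, mode)
            post = self.fine_times > 0
            t_pk = float(self.fine_times[post][np.argmax(lvl[post])])
            err = t_pk - tpl.t_peak_mean
            if abs(err) <= _FINE_DT:
                break
            mode = float(np.clip(mode - err, 2.0, 0.9 * _PULSE_SUPPORT))
            gain = self._gain_for_ratio(tpl, arrest, mode)
        return gain, mode

    def _extremum_time(self) -> float:
        post = self.fine_times > 0
        t, v = self.fine_times[post], self.level[post]
        idx = np.argmin(v) if self.template.category.endswith("_down") else np.argmax(v)
        return float(t[idx])

    @classmethod
    def cached(cls, tpl: PlantedTemplate, t_pre: float, t_post: float,
               arrest: ArrestProfile) -> "_TemplateTrace":
        key = (tpl, t_pre, t_post, arrest)
        if key not in _TRACE_CACHE:
            _TRACE_CACHE[key] = cls(tpl, t_pre, t_post, arrest)
        return _TRACE_CACHE[key]

    def level_at(self, t: np.ndarray, shift: float = 0.0) -> np.ndarray:
        return np.interp(t - shift, self.fine_times, self.level,
                         left=self.level[0], right=self.level[-1])

    def activity_at(self, t: np.ndarray, shift: float = 0.0) -> np.ndarray:
        return np.interp(t - shift, self.fine_times, self.activity,
                         left=self.activity[0], right=self.activity[-1])


def planted_trace(
    template: PlantedTemplate,
    times: np.ndarray,
    noise: NoiseModel | None = None,
    seed: int = 0,
    arrest: ArrestProfile | None = None,
    shift: float = 0.0,
) -> pd.DataFrame:
    """Single-cell planted trace: intensity, promoter activity and growth rate.

    ``times`` must include a pre-treatment (t < 0) baseline.  With ``noise``
    given, the intensity carries an OU fluctuation and per-frame measurement
    noise drawn from ``seed``; activity and growth stay noiseless (they are
    the ground truth).  Deterministic for a fixed seed.
    """
    times = np.asarray(times, float)
    if not (times < 0).any():
        raise ConfigError("planted_trace times must include a t < 0 baseline")
    arrest = arrest or ArrestProfile()
    trace = _TemplateTrace.cached(template, -float(times.min()), float(times.max()), arrest)
    level = trace.level_at(times, shift)
    intensity = level.copy()
    if noise is not None and (noise.ou_cv > 0 or noise.meas_cv > 0):
        rng = np.random.default_rng(seed)
        fluct = _ou_series(rng, len(times), times[1] - times[0], noise)
        meas = _lognormal_factor(rng, noise.meas_cv, size=len(times))
        intensity = level * fluct * meas
    return pd.DataFrame(
        {
            "time_min": times,
            "intensity": intensity,
            "level_noiseless": level,
            "activity": trace.activity_at(times, shift),
            "growth_rate": arrest.growth(times),
        }
    )


def _ou_series(rng: np.random.Generator, n: int, dt: float, noise: NoiseModel,
               shared_with: np.ndarray | None = None) -> np.ndarray:
    """Stationary lognormal OU factor with unit mean (single series)."""
    sigma = np.sqrt(np.log1p(noise.ou_cv ** 2))
    if sigma == 0:
        return np.ones(n)
    rho = np.exp(-dt / noise.ou_tau)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sigma)
    innov = rng.normal(0.0, sigma * np.sqrt(1 - rho ** 2), size=n - 1)
    for k in range(1, n):
        x[k] = rho * x[k - 1] + innov[k - 1]
    return np.exp(x - sigma ** 2 / 2)


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return np.exp(rng.normal(0.0, sigma, size=size) - sigma ** 2 / 2)


# -- track dataset ----------------------------------------------------------

REQUIRED_COLUMNS = (
    "gene", "trench_id", "cell_id", "lineage_id", "time_min",
    "barrier_count", "length_um", "area_um2", "channel", "intensity",
)


@dataclass
class TrackDataset:
    """A track table (long format, one row per cell x frame x channel) plus
    the manifest that documents how it was generated (parameters, seed and
    -- in planted mode -- the ground-truth labels, which never appear in the
    table itself)."""

    records: pd.DataFrame
    manifest: dict

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrackDataset):
            return NotImplemented
        return self.manifest == other.manifest and self.records.equals(other.records)


def write_tracks(ds: TrackDataset, path: str | Path) -> None:
    """CSV with the documented column order plus a JSON manifest sidecar."""
    path = Path(path)
    cols = [c for c in REQUIRED_COLUMNS if c in ds.records.columns]
    cols += [c for c in ds.records.columns if c not in cols]
    # %.17g keeps doubles exact across the round trip
    ds.records[cols].to_csv(path, index=False, float_format="%.17g")
    _manifest_path(path).write_text(json.dumps(ds.manifest, indent=2, sort_keys=True))


def _manifest_path(path: Path) -> Path:
    return path.with_suffix(".manifest.json")


def read_tracks(path: str | Path) -> TrackDataset:
    path = Path(path)
    try:
        records = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ParseError(f"malformed track file {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ParseError(
            f"track file {path} is missing required columns: {', '.join(missing)}"
        )
    # canonical dtypes (integral floats lose their decimal point in CSV)
    for col, dtype in (("time_min", float), ("length_um", float),
                       ("area_um2", float), ("intensity", float),
                       ("cell_id", np.int64), ("lineage_id", np.int64),
                       ("barrier_count", np.int64)):
        records[col] = records[col].astype(dtype)
    mpath = _manifest_path(path)
    manifest = json.loads(mpath.read_text()) if mpath.exists() else {}
    return TrackDataset(records=records, manifest=manifest)


# -- generation engine ------------------------------------------------------

def _simulate_geometry(rng, layout: ChannelLayout, growth_per_slot: np.ndarray):
    """Lengths, ids and lineage for every trench slot over time.

    ``growth_per_slot``: (n_slots, n_frames) instantaneous growth rates.
    Returns (lengths, cell_ids, lineage_ids) arrays of shape (n_frames, n_slots).
    """
    times = layout.times
    n_frames = times.size
    S = layout.n_trenches * layout.cells_per_trench
    dt = layout.frame_interval
    barrier = np.tile(np.arange(layout.cells_per_trench), layout.n_trenches)
    is_mother = barrier == layout.cells_per_trench - 1

    birth = _BIRTH_LENGTH * np.ones(S)
    L = birth * 2.0 ** rng.uniform(0.0, 1.0, S)
    thresh = 2.0 * birth * np.exp(rng.normal(0.0, _DIV_THRESHOLD_SD, S))
    cell_ids = np.arange(S)
    lineage = np.full(S, -1)
    next_id = S

    lengths = np.empty((n_frames, S))
    ids_out = np.empty((n_frames, S), dtype=np.int64)
    lin_out = np.empty((n_frames, S), dtype=np.int64)
    div_events = np.zeros((n_frames, S), dtype=bool)

    for k in range(n_frames):
        lengths[k] = L
        ids_out[k] = cell_ids
        lin_out[k] = lineage
        if k == n_frames - 1:
            break
        g = growth_per_slot[:, k] * (1.0 + _GROWTH_NOISE_SD * rng.standard_normal(S))
        L = L * np.exp(np.maximum(g, 0.0) * dt)
        divide = L >= thresh
        if divide.any():
            div_events[k + 1, divide] = True
            L[divide] /= 2.0
            parent = cell_ids[divide]
            new_birth = L[divide]
            thresh[divide] = 2.0 * new_birth * np.exp(
                rng.normal(0.0, _DIV_THRESHOLD_SD, int(divide.sum()))
            )
            renew = divide & ~is_mother
            n_new = int(renew.sum())
            if n_new:
                lineage[renew] = cell_ids[renew]
                cell_ids[renew] = next_id + np.arange(n_new)
                next_id += n_new
    return lengths, ids_out, lin_out, barrier, div_events


def _channel_intensity(rng, layout: ChannelLayout, noise: NoiseModel,
                       base: np.ndarray, shifts: np.ndarray | None,
                       fine_times: np.ndarray | None,
                       shared_log: np.ndarray | None):
    """Observed intensity (n_frames, n_slots) for one channel.

    ``base``: either (n_slots, n_frames) noiseless level per slot, or a fine
    grid trace to be interpolated with per-slot time ``shifts``.
    """
    times = layout.times
    n_frames = times.size
    S = layout.n_trenches * layout.cells_per_trench
    if fine_times is not None:
        tt = times[None, :] - shifts[:, None]
        u = np.interp(tt, fine_times, base, left=base[0], right=base[-1])
    else:
        u = base
    sigma = np.sqrt(np.log1p(noise.ou_cv ** 2))
    if sigma > 0:
        rho = np.exp(-layout.frame_interval / noise.ou_tau)
        s = noise.shared_fraction
        own = np.empty((S, n_frames))
        own[:, 0] = rng.normal(0.0, sigma, S)
        innov = rng.normal(0.0, sigma * np.sqrt(1 - rho ** 2), size=(S, n_frames - 1))
        for k in range(1, n_frames):
            own[:, k] = rho * own[:, k - 1] + innov[:, k - 1]
        log_f = (
            np.sqrt(s) * shared_log + np.sqrt(1.0 - s) * own
            if shared_log is not None else own
        )
        fluct = np.exp(log_f - sigma ** 2 / 2)
    else:
        fluct = 1.0
    meas = _lognormal_factor(rng, noise.meas_cv, size=(S, n_frames))
    return (u * fluct * meas).T


def _shared_log_fluct(rng, layout: ChannelLayout, noise: NoiseModel):
    """The cell-level OU log-fluctuation shared between channels."""
    sigma = np.sqrt(np.log1p(noise.ou_cv ** 2))
    S = layout.n_trenches * layout.cells_per_trench
    n_frames = layout.times.size
    if sigma == 0 or noise.shared_fraction == 0:
        return None
    rho = np.exp(-layout.frame_interval / noise.ou_tau)
    x = np.empty((S, n_frames))
    x[:, 0] = rng.normal(0.0, sigma, S)
    innov = rng.normal(0.0, sigma * np.sqrt(1 - rho ** 2), size=(S, n_frames - 1))
    for k in range(1, n_frames):
        x[:, k] = rho * x[:, k - 1] + innov[:, k - 1]
    return x


def generate_dataset(
    mode: str,
    layout: ChannelLayout,
    templates: Sequence[PlantedTemplate] | None = None,
    genes: Sequence[_model.GeneSpec] | None = None,
    noise: NoiseModel | None = None,
    params: "_model.ModelParameters | None" = None,
    protocol: "_model.TreatmentProtocol | None" = None,
    seed: int = 0,
    arrest: ArrestProfile | None = None,
    attenuation_per_cell: float = 0.3,
    gene_label: str | None = None,
) -> TrackDataset:
    """Generate one strain's track table.

    In ``planted`` mode every channel follows one :class:`PlantedTemplate`
    (same underlying trace at every trench position); in ``mechanistic`` mode
    channels follow :class:`~oxyregulon.model.GeneSpec` trajectories simulated
    per trench position with the external dose attenuated by
    ``(1 - attenuation_per_cell)^barrier_count``.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    times = layout.times
    S = layout.n_trenches * layout.cells_per_trench
    C = layout.cells_per_trench

    if mode == "planted":
        if not templates:
            raise ConfigError("planted mode needs templates")
        arrest = arrest or ArrestProfile()
        traces = [
            _TemplateTrace.cached(t, layout.t_pre, layout.t_post, arrest)
            for t in templates
        ]
        growth_profile = arrest.mean_growth(times, layout.frame_interval)
        growth_per_slot = np.tile(growth_profile, (S, 1))
        channel_names = [t.gene for t in templates]
    elif mode == "mechanistic":
        if genes is None or params is None or protocol is None:
            raise ConfigError("mechanistic mode needs genes, params and protocol")
        trajs = _model.trench_profile(
            params, list(genes), n_positions=C,
            attenuation_per_cell=attenuation_per_cell, protocol=protocol,
            t_start=float(times[0]), t_end=float(times[-1]),
            dt_out=layout.frame_interval,
        )
        growth_per_slot = np.empty((S, times.size))
        barrier_of_slot = np.tile(np.arange(C), layout.n_trenches)
        for k in range(C):
            growth_per_slot[barrier_of_slot == k] = trajs[k].mean_growth_per_frame()
        channel_names = [g.name for g in genes]
    else:
        raise ConfigError(f"unknown mode {mode!r}")

    lengths, ids_out, lin_out, barrier, _ = _simulate_geometry(rng, layout, growth_per_slot)

    # Per-slot timing jitter: sustained_up genes carry a single-cell peak-time
    # distribution (pulsatile 25.7 +/- 4.7 min, gradual 37.5 +/- 7.8 min in the
    # reference panel); each slot's trace is time-shifted so its noiseless
    # intensity peak lands on the drawn value.  One draw per slot: frontier
    # turnover re-uses the shift, which preserves the shift distribution that
    # the timing statistics read.
    frames = np.broadcast_to(times, (S, times.size)).T
    rows = []
    shared_log = _shared_log_fluct(rng, layout, noise) if mode == "planted" else None
    for ci, cname in enumerate(channel_names):
        if mode == "planted":
            tr = traces[ci]
            tpl = tr.template
            if tpl.t_peak_sd > 0 and tpl.category == "sustained_up":
                tp = rng.normal(tpl.t_peak_mean, tpl.t_peak_sd, S)
                shifts = tp - tr.t_extremum
            else:
                shifts = np.zeros(S)
            inten = _channel_intensity(
                rng, layout, noise, tr.level, shifts, tr.fine_times, shared_log
            )
        else:
            base = np.empty((S, times.size))
            for k in range(C):
                base[barrier == k] = trajs[k].series(cname)
            inten = _channel_intensity(rng, layout, noise, base, None, None, None)
        rows.append(
            pd.DataFrame(
                {
                    "gene": gene_label or cname,
                    "trench_id": np.tile(
                        np.repeat(np.arange(layout.n_trenches), C), times.size
                    ),
                    "cell_id": ids_out.ravel(),
                    "lineage_id": lin_out.ravel(),
                    "time_min": frames.ravel(),
                    "barrier_count": np.tile(barrier, times.size),
                    "length_um": lengths.ravel(),
                    "area_um2": lengths.ravel(),  # unit-width rod: area tracks length
                    "channel": cname,
                    "intensity": inten.ravel(),
                }
            )
        )
    records = pd.concat(rows, ignore_index=True)
    manifest = {
        "mode": mode,
        "seed": int(seed),
        "layout": dataclasses.asdict(layout),
        "noise": dataclasses.asdict(noise),
        "ground_truth": {
            t.gene: {"category": t.category, "dynamics": t.dynamics}
            for t in (templates or [])
        },
        "templates": [t.to_dict() for t in (templates or [])],
        "genes": [dataclasses.asdict(g) for g in (genes or [])],
        "protocol": protocol.to_dict() if protocol else None,
        "attenuation_per_cell": attenuation_per_cell if mode == "mechanistic" else None,
        "arrest": dataclasses.asdict(arrest) if arrest else None,
    }
    return TrackDataset(records=records, manifest=manifest)


def generate_regulon(
    templates: Sequence[PlantedTemplate],
    layout: ChannelLayout,
    noise: NoiseModel | None = None,
    seed: int = 0,
    arrest: ArrestProfile | None = None,
) -> TrackDataset:
    """A multi-strain planted dataset: one single-reporter strain per gene.

    Each gene gets its own trenches (as in the real experiments, where each
    transcriptional reporter is a separate strain); trench and cell ids are
    namespaced by gene.  Ground truth for every gene lives in the manifest.
    """
    noise = noise or NoiseModel()
    child_seeds = np.random.SeedSequence(seed).generate_state(len(templates))
    parts = []
    for tpl, child in zip(templates, child_seeds):
        ds = generate_dataset(
            "planted", layout, templates=[tpl], noise=noise,
            seed=int(child), arrest=arrest,
        )
        df = ds.records
        df["trench_id"] = tpl.gene + ":" + df["trench_id"].astype(str)
        df["channel"] = "fluor"
        parts.append(df)
    records = pd.concat(parts, ignore_index=True)
    manifest = {
        "mode": "planted_regulon",
        "seed": int(seed),
        "layout": dataclasses.asdict(layout),
        "noise": dataclasses.asdict(noise),
        "ground_truth": {
            t.gene: {"category": t.category, "dynamics": t.dynamics} for t in templates
        },
        "templates": [t.to_dict() for t in templates],
    }
    return TrackDataset(records=records, manifest=manifest)


def generate_timing_cells(
    n_cells: int,
    t_peak_mean: float,
    t_peak_sd: float,
    noise: NoiseModel | None = None,
    seed: int = 0,
    basal: float = 200.0,
    amplitude: float = 2.0,
    peak_width: float = 12.0,
    layout: ChannelLayout | None = None,
) -> pd.DataFrame:
    """Mother-cell traces for single-cell peak-*timing* studies.

    Each cell's intensity carries one Gaussian-in-time bump,
    ``basal * (1 + amplitude * exp(-(t - tp)^2 / (2 w^2)))`` for t > 0, with
    its per-cell peak time ``tp`` drawn from Normal(t_peak_mean, t_peak_sd),
    then the usual OU and measurement noise.  The symmetric, clearly
    prominent peak makes the peak time identifiable: the argmax of a
    flat-topped expression trace (whose post-peak decay is bounded by the
    dilution rate) is not, under slow multiplicative fluctuations.  The shape
    represents a reporter pulse with fast post-peak clearance; it is a
    calibration construct for the timing statistic, not a dilution model.

    Returns a long table with ``cell_id``, ``time_min``, ``intensity``.
    """
    noise = noise or NoiseModel()
    layout = layout or ChannelLayout(n_trenches=n_cells, cells_per_trench=1)
    rng = np.random.default_rng(seed)
    times = layout.times
    tp = rng.normal(t_peak_mean, t_peak_sd, n_cells)
    tt = np.broadcast_to(times, (n_cells, times.size))
    bump = amplitude * np.exp(-((tt - tp[:, None]) ** 2) / (2.0 * peak_width ** 2))
    level = basal * (1.0 + np.where(tt > 0, bump, 0.0))
    sigma = np.sqrt(np.log1p(noise.ou_cv ** 2))
    if sigma > 0:
        rho = np.exp(-layout.frame_interval / noise.ou_tau)
        x = np.empty((n_cells, times.size))
        x[:, 0] = rng.normal(0.0, sigma, n_cells)
        innov = rng.normal(0.0, sigma * np.sqrt(1 - rho ** 2),
                           size=(n_cells, times.size - 1))
        for k in range(1, times.size):
            x[:, k] = rho * x[:, k - 1] + innov[:, k - 1]
        level = level * np.exp(x - sigma ** 2 / 2)
    level = level * _lognormal_factor(rng, noise.meas_cv, size=level.shape)
    return pd.DataFrame(
        {
            "cell_id": np.repeat(np.arange(n_cells), times.size),
            "time_min": np.tile(times, n_cells),
            "intensity": level.ravel(),
        }
    )


# -- reference panels -------------------------------------------------------

REGULON_CATEGORY_COUNTS = {
    "sustained_up": 11,
    "transient_up": 2,
    "sustained_down": 8,
    "transient_down": 7,
    "none": 3,
}

_PULSATILE_GENES = ("katG", "yaaA", "clpS", "hemH", "uxuA", "poxB", "yaiA")
_GRADUAL_GENES = ("grxA", "trxC", "fur", "ahpC")
_NONE_GENES = ("hcp", "yfdL", "ybjN")


def regulon_panel_templates() -> list[PlantedTemplate]:
    """The 31-promoter panel with the category structure observed for the
    E. coli OxyR regulon: 11 sustained upregulated (7 pulsatile with a
    level peak/steady ratio of 3 peaking at 25.7 +/- 4.7 min, 4 gradual with
    ratio 1.5 peaking at 37.5 +/- 7.8 min), 2 transient up, 8 sustained
    down, 7 transient down and 3 with no significant regulation."""
    out: list[PlantedTemplate] = []

    def basal(i: int) -> float:
        return 150.0 + 17.0 * i

    i = 0
    for g in _PULSATILE_GENES:
        out.append(PlantedTemplate(
            gene=g, category="sustained_up", dynamics="pulsatile",
            peak_over_steady=3.0, t_peak_mean=25.7, t_peak_sd=4.7,
            amplitude=1.5, basal=basal(i)))
        i += 1
    for g in _GRADUAL_GENES:
        out.append(PlantedTemplate(
            gene=g, category="sustained_up", dynamics="gradual",
            peak_over_steady=1.5, t_peak_mean=37.5, t_peak_sd=7.8,
            amplitude=2.5, basal=basal(i)))
        i += 1
    for g in ("tup1", "tup2"):
        out.append(PlantedTemplate(
            gene=g, category="transient_up", amplitude=2.5,
            t_peak_mean=25.0, t_peak_sd=5.0, basal=basal(i)))
        i += 1
    for g in ("fhuF", "sdn2", "sdn3", "sdn4", "sdn5", "sdn6", "sdn7", "sdn8"):
        out.append(PlantedTemplate(
            gene=g, category="sustained_down", amplitude=0.5,
            t_peak_mean=25.0, t_peak_sd=5.0, basal=basal(i)))
        i += 1
    for g in ("tdn1", "tdn2", "tdn3", "tdn4", "tdn5", "tdn6", "tdn7"):
        out.append(PlantedTemplate(
            gene=g, category="transient_down", amplitude=0.45,
            t_peak_mean=25.0, t_peak_sd=5.0, basal=basal(i)))
        i += 1
    for g in _NONE_GENES:
        out.append(PlantedTemplate(
            gene=g, category="none", amplitude=1.0, basal=basal(i)))
        i += 1
    assert len(out) == 31
    return out


def dose_panel_templates(
    doses: Sequence[float] = (25.0, 50.0, 100.0),
) -> dict[tuple[str, float], PlantedTemplate]:
    """Planted multi-dose panel for the peak-vs-steady regression.

    The 7 pulsatile genes carry a level peak/steady ratio of 3 at every dose
    and the 4 gradual genes a ratio of 1.5, with per-gene dose sensitivities
    of the steady level, so the (steady, peak) points of each gene fall on a
    line of slope equal to its class ratio.
    """
    out: dict[tuple[str, float], PlantedTemplate] = {}
    for i, g in enumerate(_PULSATILE_GENES):
        beta = 0.35 + 0.05 * i
        for d in doses:
            out[(g, d)] = PlantedTemplate(
                gene=g, category="sustained_up", dynamics="pulsatile",
                peak_over_steady=3.0, t_peak_mean=25.7, t_peak_sd=4.7,
                amplitude=1.0 + beta * d / 100.0, basal=180.0 + 20.0 * i)
    for i, g in enumerate(_GRADUAL_GENES):
        beta = 1.0 + 0.25 * i
        for d in doses:
            out[(g, d)] = PlantedTemplate(
                gene=g, category="sustained_up", dynamics="gradual",
                peak_over_steady=1.5, t_peak_mean=37.5, t_peak_sd=7.8,
                amplitude=1.0 + beta * d / 100.0, basal=220.0 + 20.0 * i)
    return out
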
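"""Regulation-category calling for the OxyR regulon.

Genes are classified from growth-corrected promoter activity with two-sided
Mann-Whitney rank tests comparing per-cell window means against the
pre-treatment basal sample: one test in the early "peak" window (9-60 min
post treatment) and one at steady state (120-180 min).  The two signed,
thresholded outcomes map onto five categories:

====================  =========================================
(peak, steady) calls  category
====================  =========================================
(up, up)              sustained_up
(up, none)            transient_up
(down, down)          sustained_down
(down, none)          transient_down
(none, none)          none
discordant signs      direction of the peak window, sustained,
                      flagged ``discordant``
====================  =========================================

Sustained upregulated genes are further split into *pulsatile* and
*gradual* dynamics by the slope of an ordinary-least-squares regression of
peak expression level against steady-state level across treatment doses:
pulsatile genes cluster near a peak/steady ratio of ~3, gradually
responding genes near ~1.5, and the default decision threshold 2.12 is the
geometric mean of the two class ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .metrics import AnalysisWindows, add_activity_columns, per_cell_window_means

__all__ = [
    "WindowCall",
    "CategoryCall",
    "DynamicsCall",
    "RegressionFit",
    "RegulonReport",
    "window_test",
    "activity_units",
    "classify_units",
    "assign_category",
    "classify_gene",
    "classify_dataset",
    "peak_vs_steady_regression",
    "split_pulsatile_gradual",
    "dose_sensitivity",
    "benjamini_hochberg",
]

DEFAULT_ALPHA = 0.05
DEFAULT_RATIO_THRESHOLD = 2.12  # geometric mean of the ~3 and ~1.5 class ratios
_EXACT_MAX_N = 8


@dataclass(frozen=True)
class WindowCall:
    direction: str  # "up" | "down" | "none"
    p: float
    n_basal: int
    n_window: int


@dataclass(frozen=True)
class CategoryCall:
    gene: str
    direction: str
    persistence: str  # "sustained" | "transient" | "none"
    p_peak: float
    p_steady: float
    category: str
    discordant: bool = False


@dataclass(frozen=True)
class DynamicsCall:
    gene: str
    peak_over_steady: float
    dynamics: str  # "pulsatile" | "gradual"
    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float


def window_test(
    activity_basal: Sequence[float],
    activity_window: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
) -> WindowCall:
    """Two-sided Mann-Whitney comparison of a response window against basal.

    Exact enumeration is used when both samples have at most 8 untied
    values; otherwise the normal approximation with tie correction.  The
    direction is the sign of the median difference, forced to "none" when
    p > alpha.
    """
    basal = np.asarray(activity_basal, float)
    window = np.asarray(activity_window, float)
    basal = basal[~np.isnan(basal)]
    window = window[~np.isnan(window)]
    if basal.size == 0 or window.size == 0:
        raise DataError("window_test: empty sample")
    if basal.size < 5 or window.size < 5:
        raise DataError(
            f"window_test needs >= 5 values per sample, got {basal.size}/{window.size}"
        )
    pooled = np.concatenate([basal, window])
    has_ties = np.unique(pooled).size < pooled.size
    method = (
        "exact"
        if (max(basal.size, window.size) <= _EXACT_MAX_N and not has_ties)
        else "asymptotic"
    )
    res = stats.mannwhitneyu(window, basal, alternative="two-sided", method=method)
    p = float(res.pvalue)
    diff = float(np.median(window) - np.median(basal))
    if p > alpha or diff == 0:
        direction = "none"
    else:
        direction = "up" if diff > 0 else "down"
    return WindowCall(direction=direction, p=p, n_basal=basal.size, n_window=window.size)


def assign_category(gene: str, peak: WindowCall, steady: WindowCall) -> CategoryCall:
    """Map the (peak, steady) window calls onto the five-category taxonomy."""
    pd_, sd_ = peak.direction, steady.direction
    discordant = False
    if pd_ == "none" and sd_ == "none":
        direction, persistence = "none", "none"
    elif pd_ != "none" and sd_ == "none":
        direction, persistence = pd_, "transient"
    elif pd_ == sd_:
        direction, persistence = pd_, "sustained"
    elif pd_ == "none":
        # change only at steady state: a late, sustained response
        direction, persistence = sd_, "sustained"
    else:
        # opposite signs (e.g. down at peak, up at steady): direction follows
        # the peak window, flagged for inspection
        direction, persistence = pd_, "sustained"
        discordant = True
    category = "none" if direction == "none" else f"{persistence}_{direction}"
    return CategoryCall(
        gene=gene, direction=direction, persistence=persistence,
        p_peak=peak.p, p_steady=steady.p, category=category, discordant=discordant,
    )


def classify_gene(
    gene: str,
    basal: Sequence[float],
    peak_window: Sequence[float],
    steady_window: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
) -> CategoryCall:
    peak = window_test(basal, peak_window, alpha)
    steady = window_test(basal, steady_window, alpha)
    return assign_category(gene, peak, steady)


@dataclass
class RegulonReport:
    """Per-gene category calls plus aggregate counts (and, when dose data
    exist, the pulsatile/gradual dynamics calls)."""

    calls: list[CategoryCall]
    dynamics: list[DynamicsCall] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in
               ("sustained_up", "transient_up", "sustained_down", "transient_down", "none")}
        for call in self.calls:
            out[call.category] += 1
        return out

    @property
    def n_genes(self) -> int:
        return len(self.calls)

    def to_frame(self) -> pd.DataFrame:
        rows = [vars(c).copy() for c in self.calls]
        dyn = {d.gene: d for d in self.dynamics}
        for r in rows:
            d = dyn.get(r["gene"])
            r["dynamics"] = d.dynamics if d else ""
            r["peak_over_steady"] = d.peak_over_steady if d else np.nan
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        counts = self.counts
        assert sum(counts.values()) == self.n_genes
        return {
            "n_genes": self.n_genes,
            "category_counts": counts,
            "transient_total": counts["transient_up"] + counts["transient_down"],
            "dynamics_counts": {
                "pulsatile": sum(d.dynamics == "pulsatile" for d in self.dynamics),
                "gradual": sum(d.dynamics == "gradual" for d in self.dynamics),
            },
        }


def activity_units(
    records: pd.DataFrame,
    windows: AnalysisWindows | None = None,
    min_frames: int = 10,
) -> pd.DataFrame:
    """Per-cell promoter-activity window means: the rank-test units.

    One row per (gene, window, cell) with the cell's mean activity over the
    frames inside the window (frontier cells only); windows are labelled
    ``basal``, ``peak`` and ``steady``.  ``min_frames`` requires cells to
    cover a window substantially before they count as a unit: activity means
    over few frames are dominated by frame-differencing noise and make the
    unit distributions heterogeneous.
    """
    windows = windows or AnalysisWindows()
    df = add_activity_columns(records)
    rows = []
    for gene, sub in df.groupby("gene", sort=True):
        for label, win in (
            ("basal", windows.basal),
            ("peak", windows.peak_activity),
            ("steady", windows.steady_activity),
        ):
            means = per_cell_window_means(sub, "activity", win, min_frames)
            rows.append(pd.DataFrame({
                "gene": gene,
                "window": label,
                "cell_id": means.index,
                "activity_mean": means.to_numpy(),
            }))
    return pd.concat(rows, ignore_index=True)


def classify_units(
    units: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    adjust: str | None = None,
) -> RegulonReport:
    """Run the windowed rank tests on a per-cell units table (see
    :func:`activity_units`) and assign the five-way categories."""
    raw: list[tuple[str, WindowCall, WindowCall]] = []
    for gene, sub in units.groupby("gene", sort=True):
        samples = {
            w: s["activity_mean"].to_numpy() for w, s in sub.groupby("window")
        }
        for w in ("basal", "peak", "steady"):
            if w not in samples:
                raise DataError(f"gene {gene!r}: missing window {w!r} in units table")
        raw.append((
            gene,
            window_test(samples["basal"], samples["peak"], alpha),
            window_test(samples["basal"], samples["steady"], alpha),
        ))
    if adjust == "bh":
        pvals = [p for _, pk, st in raw for p in (pk.p, st.p)]
        adj = benjamini_hochberg(pvals)
        fixed = []
        for i, (gene, pk, st) in enumerate(raw):
            fixed.append((
                gene,
                _recalled(pk, adj[2 * i], alpha),
                _recalled(st, adj[2 * i + 1], alpha),
            ))
        raw = fixed
    calls = [assign_category(gene, pk, st) for gene, pk, st in raw]
    return RegulonReport(calls=calls)


def classify_dataset(
    records: pd.DataFrame,
    windows: AnalysisWindows | None = None,
    alpha: float = DEFAULT_ALPHA,
    min_frames: int = 10,
    adjust: str | None = None,
) -> RegulonReport:
    """Classify every gene of a track table.

    Convenience wrapper: :func:`activity_units` followed by
    :func:`classify_units`.  ``adjust="bh"`` applies a Benjamini-Hochberg
    correction across all window tests (off by default: the per-gene tests
    are reported as-is, matching the per-gene significance convention of the
    source analyses).
    """
    units = activity_units(records, windows, min_frames)
    return classify_units(units, alpha, adjust)


def _recalled(call: WindowCall, p_adj: float, alpha: float) -> WindowCall:
    direction = "none" if p_adj > alpha else call.direction
    return WindowCall(direction=direction, p=p_adj,
                      n_basal=call.n_basal, n_window=call.n_window)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(pvalues, float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


# -- pulsatile vs gradual ---------------------------------------------------

def peak_vs_steady_regression(points: Sequence[tuple[float, float]]) -> RegressionFit:
    """OLS fit of peak level against steady-state level across doses.

    ``points`` are (steady, peak) pairs, typically one per treatment dose.
    The fitted slope is the gene's peak/steady ratio estimate.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise DataError("peak_vs_steady_regression needs >= 3 (steady, peak) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise DataError("degenerate regression: steady levels have no variance")
    fit = stats.linregress(x, y)
    return RegressionFit(slope=float(fit.slope), intercept=float(fit.intercept),
                         r_squared=float(fit.rvalue ** 2))


def split_pulsatile_gradual(
    ratios: Mapping[str, RegressionFit] | Mapping[str, float],
    threshold: float = DEFAULT_RATIO_THRESHOLD,
) -> list[DynamicsCall]:
    """Label genes pulsatile (ratio >= threshold) or gradual (< threshold)."""
    out = []
    for gene, fit in ratios.items():
        if isinstance(fit, RegressionFit):
            ratio, slope, intercept, r2 = fit.slope, fit.slope, fit.intercept, fit.r_squared
        else:
            ratio = float(fit)
            if not np.isfinite(ratio):
                raise DataError(f"non-finite peak/steady ratio for gene {gene!r}")
            slope, intercept, r2 = ratio, np.nan, np.nan
        out.append(DynamicsCall(
            gene=gene, peak_over_steady=ratio,
            dynamics="pulsatile" if ratio >= threshold else "gradual",
            slope=slope, intercept=intercept, r_squared=r2,
        ))
    return out


def dose_sensitivity(
    dose_table: pd.DataFrame,
) -> pd.DataFrame:
    """OLS slopes of basal-normalised peak and steady levels against dose.

    ``dose_table`` needs columns ``gene``, ``dose``, ``peak_rel``,
    ``steady_rel`` with >= 3 doses per gene.  Returns one row per gene with
    ``peak_slope`` and ``steady_slope``.
    """
    rows = []
    for gene, sub in dose_table.groupby("gene", sort=True):
        if sub["dose"].nunique() < 3:
            raise DataError(f"gene {gene!r}: dose_sensitivity needs >= 3 doses")
        fit_p = stats.linregress(sub["dose"], sub["peak_rel"])
        fit_s = stats.linregress(sub["dose"], sub["steady_rel"])
        rows.append({"gene": gene, "peak_slope": float(fit_p.slope),
                     "steady_slope": float(fit_s.slope)})
    return pd.DataFrame(rows)
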
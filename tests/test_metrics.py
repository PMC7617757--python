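"""Trace statistics: rate formulas, window conventions, percentile and CV
oracles, spatial normalisation and cross-correlation."""

import numpy as np
import pandas as pd
import pytest

from oxyregulon import AnalysisWindows, DataError
from oxyregulon.metrics import (
    add_activity_columns,
    cell_peak,
    cell_time_to_peak,
    coefficient_of_variation,
    cross_correlation,
    elongation_rate,
    expression_rate,
    gene_to_gene_cv,
    per_cell_window_means,
    population_peak,
    population_steady,
    promoter_activity,
    relative_spatial_profile,
    trace_peak,
    trace_steady,
)

W = AnalysisWindows()


# -- per-frame rates --------------------------------------------------------

def test_elongation_rate_examples():
    t = np.array([0.0, 3.0, 6.0])
    assert np.allclose(elongation_rate(t, [2.0, 2.0, 2.0])[1:], 0.0)
    L = 1.7 * np.exp(0.012 * t)
    assert np.allclose(elongation_rate(t, L)[1:], 0.012)
    r = elongation_rate([0.0, 3.0], [2.00, 2.06])
    assert r[1] == pytest.approx(np.log(2.06 / 2.00) / 3.0)  # 0.0098529 min^-1
    assert r[1] == pytest.approx(0.009853, abs=1e-6)


def test_elongation_rate_skips_division_frames():
    t = np.arange(0.0, 15.0, 3.0)
    L = np.array([2.0, 2.2, 2.4, 1.25, 1.4])  # division between frames 2 and 3
    r = elongation_rate(t, L)
    assert np.isnan(r[0]) and np.isnan(r[3])
    assert np.isfinite(r[[1, 2, 4]]).all()


def test_elongation_rate_rejects_bad_lengths():
    with pytest.raises(DataError):
        elongation_rate([0, 3], [2.0, -1.0])
    with pytest.raises(DataError):
        elongation_rate([0], [2.0])


def test_expression_rate_examples():
    assert expression_rate([0.0, 3.0], [100.0, 103.0])[1] == pytest.approx(1.0)
    assert np.allclose(expression_rate([0, 3, 6], [5.0, 5.0, 5.0])[1:], 0.0)


def test_promoter_activity_identity_and_limits(rng):
    t = np.arange(0.0, 60.0, 3.0)
    L = 2.0 * np.exp(0.01 * t) * rng.uniform(0.95, 1.05, t.size)
    I = 100 + 10 * rng.standard_normal(t.size)
    act = promoter_activity(t, L, I)
    resid = act - (I * elongation_rate(t, L) + expression_rate(t, I))
    assert np.all((resid == 0) | np.isnan(resid))
    # steady exponential growth with constant concentration: activity = I * g
    I0 = np.full(t.size, 50.0)
    act = promoter_activity(t, 2.0 * np.exp(0.012 * t), I0)
    assert np.allclose(act[1:], 50.0 * 0.012)
    # growth arrest with intensity rising at slope s: activity = s
    act = promoter_activity(t, np.full(t.size, 2.0), 10.0 + 0.7 * t)
    assert np.allclose(act[1:], 0.7)


# -- percentile / window conventions ----------------------------------------

def _percentile_oracle(values, q=90.0):
    """Linear interpolation between order statistics, from scratch."""
    v = np.sort(np.asarray(values, float))
    pos = (len(v) - 1) * q / 100.0
    lo, frac = int(np.floor(pos)), pos % 1.0
    return v[lo] if frac == 0 else v[lo] * (1 - frac) + v[min(lo + 1, len(v) - 1)] * frac


def test_trace_peak_matches_percentile_oracle(rng):
    t = np.arange(12.0, 93.0, 3.0)  # 27 frames inside the peak window
    vals = np.arange(1.0, 28.0)
    assert trace_peak(t, vals, (12, 90)) == pytest.approx(_percentile_oracle(vals))
    for _ in range(25):
        v = rng.uniform(0, 100, rng.integers(2, 100))
        tt = np.linspace(12, 90, v.size)
        assert trace_peak(tt, v, (12, 90)) == pytest.approx(_percentile_oracle(v))


def test_population_peak_matches_oracle(rng):
    cells = []
    for cid in range(40):
        tt = np.arange(0.0, 120.0, 3.0)
        cells.append(pd.DataFrame({
            "cell_id": cid, "time_min": tt, "barrier_count": 0,
            "intensity": rng.uniform(50, 150) + rng.normal(0, 5, tt.size)}))
    df = pd.concat(cells)
    means = per_cell_window_means(df, "intensity", W.peak_level, min_frames=5)
    assert population_peak(df, W) == pytest.approx(_percentile_oracle(means))
    assert population_steady(df, W.__class__(steady_level=(90.0, None))) == pytest.approx(
        per_cell_window_means(df, "intensity", (90.0, None)).mean())


def test_window_containment_sentinel_poisoning():
    """Out-of-window frames must never leak into a statistic."""
    t = np.arange(-120.0, 363.0, 3.0)
    clean = np.full(t.size, 10.0)
    poisoned = clean.copy()
    outside = (t < 12) | (t > 90)
    poisoned[outside] = 1e12
    assert trace_peak(t, poisoned, (12, 90)) == trace_peak(t, clean, (12, 90))
    poisoned2 = clean.copy()
    poisoned2[t < 150] = -1e12
    assert trace_steady(t, poisoned2, (150, None)) == trace_steady(t, clean, (150, None))
    poisoned3 = clean.copy()
    poisoned3[(t <= 0) | (t > 100)] = 1e12  # sentinel outside the horizon
    assert cell_time_to_peak(t, np.where((t > 0) & (t <= 100), np.sin(t / 30), 1e12),
                             W) == cell_time_to_peak(
        np.clip(t, None, None), np.where((t > 0) & (t <= 100), np.sin(t / 30), -1e12), W)


def test_basal_window_includes_treatment_start_frame():
    t = np.array([-6.0, -3.0, 0.0, 3.0])
    vals = np.array([1.0, 1.0, 4.0, 9.0])
    # t = 0 belongs to basal: mean over {1, 1, 4}
    assert trace_steady(t, vals, W.basal) == pytest.approx(2.0)


# -- single-cell summaries --------------------------------------------------

def test_cell_time_to_peak_conventions():
    t = np.arange(-12.0, 363.0, 3.0)
    rising = t.astype(float)
    assert cell_time_to_peak(t, rising, W) == 99.0  # last frame inside horizon
    flat = np.ones_like(t)
    assert cell_time_to_peak(t, flat, W) == 3.0  # ties break earliest
    with pytest.raises(DataError):
        cell_time_to_peak(np.array([-9.0, -3.0]), np.array([1.0, 2.0]), W)


def test_cell_peak_subtracts_basal():
    t = np.arange(-30.0, 120.0, 3.0)
    flat = np.full(t.size, 7.0)
    assert cell_peak(t, flat, W) == pytest.approx(0.0)
    bump = flat + np.where((t >= 18) & (t <= 90), 5.0, 0.0)
    assert cell_peak(t, bump, W) == pytest.approx(5.0)


# -- variability ------------------------------------------------------------

def test_coefficient_of_variation_conventions():
    assert coefficient_of_variation([4.0, 4.0, 4.0]) == 0.0
    # sample (n-1) standard deviation: sd({1,3}) = sqrt(2), mean = 2
    assert coefficient_of_variation([1.0, 3.0]) == pytest.approx(np.sqrt(2) / 2)
    with pytest.raises(DataError):
        coefficient_of_variation([5.0])
    with pytest.raises(DataError):
        coefficient_of_variation([-1.0, 1.0])


def test_gene_to_gene_cv_peaks_in_transient_window():
    """Across the planted regulon, gene-to-gene variability is maximal during
    the transient peak, intermediate at steady state, minimal before
    treatment."""
    from oxyregulon.synthetic import planted_trace, regulon_panel_templates

    times = np.arange(-120.0, 360.1, 3.0)
    traces = {}
    for tpl in regulon_panel_templates():
        traces[tpl.gene] = planted_trace(tpl, times)["level_noiseless"].to_numpy()
    mat = pd.DataFrame(traces, index=times)
    cv = gene_to_gene_cv(mat)
    cv_basal = cv[cv.index <= 0].mean()
    cv_peak = cv[(cv.index >= 12) & (cv.index <= 90)].max()
    cv_steady = cv[cv.index >= 150].mean()
    assert cv_peak > cv_steady > cv_basal


# -- space ------------------------------------------------------------------

def test_relative_spatial_profile_uniform_is_one():
    rows = []
    for trench in range(3):
        for k in range(4):
            for t in (15.0, 18.0):
                rows.append({"trench_id": trench, "time_min": t,
                             "barrier_count": k, "intensity": 50.0})
    prof = relative_spatial_profile(pd.DataFrame(rows), window=(12, 90))
    assert np.allclose(prof.to_numpy(), 1.0)
    assert prof.loc[0] == 1.0


def test_relative_spatial_profile_toy_oracle():
    # trench 0: frontier 10, k=1 cell 5 -> ratio 0.5; trench 1: 20 and 15 -> 0.75
    rows = [
        {"trench_id": 0, "time_min": 15.0, "barrier_count": 0, "intensity": 10.0},
        {"trench_id": 0, "time_min": 15.0, "barrier_count": 1, "intensity": 5.0},
        {"trench_id": 1, "time_min": 15.0, "barrier_count": 0, "intensity": 20.0},
        {"trench_id": 1, "time_min": 15.0, "barrier_count": 1, "intensity": 15.0},
    ]
    prof = relative_spatial_profile(pd.DataFrame(rows), window=(12, 90))
    assert prof.loc[1] == pytest.approx((0.5 + 0.75) / 2)


def test_relative_spatial_profile_warns_on_missing_frontier():
    rows = [
        {"trench_id": 0, "time_min": 15.0, "barrier_count": 1, "intensity": 5.0},
        {"trench_id": 1, "time_min": 15.0, "barrier_count": 0, "intensity": 20.0},
        {"trench_id": 1, "time_min": 15.0, "barrier_count": 1, "intensity": 10.0},
    ]
    with pytest.warns(UserWarning, match="lacks a frontier"):
        prof = relative_spatial_profile(pd.DataFrame(rows), window=(12, 90))
    assert prof.loc[1] == pytest.approx(0.5)


# -- cross-correlation ------------------------------------------------------

def test_cross_correlation_self_is_one(rng):
    x = rng.standard_normal(120)
    cc = cross_correlation(x, x, max_lag=10)
    assert cc.loc[0.0] == pytest.approx(1.0)


def test_cross_correlation_symmetry(rng):
    x = rng.standard_normal(150)
    y = rng.standard_normal(150)
    ab = cross_correlation(x, y, max_lag=8)
    ba = cross_correlation(y, x, max_lag=8)
    assert np.allclose(ab.to_numpy(), ba.to_numpy()[::-1], atol=1e-12)


def test_cross_correlation_null_case(rng):
    xs = [rng.standard_normal(100) for _ in range(100)]
    ys = [rng.standard_normal(100) for _ in range(100)]
    cc = cross_correlation(xs, ys, max_lag=5)
    # lag-0 mean over 100 independent trenches: within 3 s.e. of 0
    assert abs(cc.loc[0.0]) < 3.0 / np.sqrt(100 * 100)


def test_cross_correlation_detects_shared_fluctuations():
    from oxyregulon import ChannelLayout, NoiseModel, generate_dataset
    from oxyregulon.synthetic import PlantedTemplate

    layout = ChannelLayout(n_trenches=40, cells_per_trench=2)
    tpls = [PlantedTemplate(gene=g, category="none", basal=200.0) for g in ("a", "b")]

    def mother_pairs(shared):
        noise = NoiseModel(meas_cv=0.02, ou_cv=0.15, shared_fraction=shared)
        ds = generate_dataset("planted", layout, templates=tpls, noise=noise, seed=8)
        rec = ds.records[(ds.records.barrier_count == 1)
                         & (ds.records.time_min >= 150)]
        xs, ys = [], []
        for _, sub in rec.groupby("trench_id"):
            wide = sub.pivot_table(index="time_min", columns="channel",
                                   values="intensity").sort_index()
            xs.append(wide["a"].to_numpy())
            ys.append(wide["b"].to_numpy())
        return cross_correlation(xs, ys, max_lag=5)

    coupled = mother_pairs(0.8)
    control = mother_pairs(0.0)
    assert coupled.loc[0.0] > control.loc[0.0] + 0.3


def test_cross_correlation_rejects_short_segments(rng):
    with pytest.raises(DataError):
        cross_correlation(rng.standard_normal(10), rng.standard_normal(10), max_lag=8)


# -- vectorised activity table ---------------------------------------------

def test_add_activity_columns_matches_per_trace_formulas(rng):
    t = np.arange(0.0, 60.0, 3.0)
    frames = []
    for cid in range(3):
        L = 2.0 * np.exp(0.01 * t)
        I = 100 + rng.normal(0, 5, t.size)
        frames.append(pd.DataFrame({
            "gene": "g", "channel": "c", "cell_id": cid, "time_min": t,
            "length_um": L, "area_um2": L, "intensity": I}))
    df = add_activity_columns(pd.concat(frames, ignore_index=True))
    for cid, sub in df.groupby("cell_id"):
        sub = sub.sort_values("time_min")
        expected = promoter_activity(sub["time_min"].to_numpy(),
                                     sub["length_um"].to_numpy(),
                                     sub["intensity"].to_numpy())
        got = sub["activity"].to_numpy()
        assert np.allclose(got[1:], expected[1:]) and np.isnan(got[0])


# -- hypothesis property tests ----------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1e4), min_size=2, max_size=100))
def test_trace_peak_percentile_property(values):
    t = np.linspace(12.0, 90.0, len(values))
    v = np.asarray(values)
    peak = trace_peak(t, v, (12, 90))
    assert v.min() <= peak <= v.max()
    assert peak == pytest.approx(_percentile_oracle(v), abs=1e-9 * (1 + v.max()))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.floats(min_value=1e-4, max_value=0.05),
       st.floats(min_value=0.1, max_value=5.0))
def test_elongation_rate_exact_for_exponential_growth(rate, L0):
    t = np.arange(0.0, 60.0, 3.0)
    r = elongation_rate(t, L0 * np.exp(rate * t))
    assert np.allclose(r[1:], rate, rtol=1e-9)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_promoter_activity_identity_property(seed):
    gen = np.random.default_rng(seed)
    t = np.arange(0.0, 45.0, 3.0)
    L = np.exp(gen.normal(0.7, 0.2, t.size))
    I = np.abs(gen.normal(100, 20, t.size))
    act = promoter_activity(t, L, I)
    resid = act - (I * elongation_rate(t, L) + expression_rate(t, I))
    assert np.all((resid == 0) | np.isnan(resid))
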
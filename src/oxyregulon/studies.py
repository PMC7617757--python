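"""Pre-configured in-silico studies.

Each function runs one complete, seeded experiment at the package's
reference scale and returns plain dictionaries of results.  They are the
building blocks of the reproduction script and of the acceptance test
suite; parameters default to the study conditions documented in the
methods note.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import linregress

from . import model as M
from .classify import (
    DEFAULT_ALPHA,
    DEFAULT_RATIO_THRESHOLD,
    classify_dataset,
    peak_vs_steady_regression,
    split_pulsatile_gradual,
)
from .metrics import (
    AnalysisWindows,
    cell_time_to_peak,
    population_peak,
    population_steady,
    promoter_activity,
)
from .synthetic import (
    ChannelLayout,
    NoiseModel,
    dose_panel_templates,
    generate_dataset,
    generate_regulon,
    generate_timing_cells,
    regulon_panel_templates,
)

__all__ = [
    "classify_planted_regulon",
    "dose_panel_regression",
    "reporter_panel_pulse",
    "timing_recovery",
    "TIMING_CLASSES",
]

#: published single-cell peak-time distributions (min): pulsatile and gradual
TIMING_CLASSES = {
    "pulsatile": {"mean": 25.7, "sd": 4.7, "peak_width": 12.0},
    "gradual": {"mean": 37.5, "sd": 7.8, "peak_width": 16.0},
}


def classify_planted_regulon(
    seed: int,
    n_trenches: int = 300,
    cells_per_trench: int = 2,
    noise: NoiseModel | None = None,
    alpha: float = DEFAULT_ALPHA,
    min_frames: int = 10,
) -> dict:
    """Generate the planted 31-gene regulon and classify it.

    Returns the category counts, the per-gene calls and the fraction of
    genes whose call matches the planted ground truth.
    """
    templates = regulon_panel_templates()
    layout = ChannelLayout(n_trenches=n_trenches, cells_per_trench=cells_per_trench)
    ds = generate_regulon(templates, layout, noise or NoiseModel(), seed=seed)
    report = classify_dataset(ds.records, alpha=alpha, min_frames=min_frames)
    truth = ds.manifest["ground_truth"]
    correct = sum(c.category == truth[c.gene]["category"] for c in report.calls)
    counts = report.counts
    return {
        "counts": counts,
        "transient_total": counts["transient_up"] + counts["transient_down"],
        "accuracy": correct / report.n_genes,
        "report": report,
        "truth": {g: v["category"] for g, v in truth.items()},
    }


def dose_panel_regression(
    seed: int,
    n_trenches: int = 100,
    doses: tuple[float, ...] = (25.0, 50.0, 100.0),
    noise: NoiseModel | None = None,
    threshold: float = DEFAULT_RATIO_THRESHOLD,
) -> dict:
    """Planted multi-dose panel: per-gene and per-class peak-vs-steady fits.

    Generates one dataset per (gene, dose), summarises basal-normalised peak
    (90th percentile, 12-90 min) and steady (mean from 150 min) levels of
    frontier cells, fits the per-gene regression across doses (the
    pulsatile/gradual split) and one pooled regression per class (the class
    slope).
    """
    windows = AnalysisWindows()
    panel = dose_panel_templates(doses)
    layout = ChannelLayout(n_trenches=n_trenches, cells_per_trench=2)
    noise = noise or NoiseModel()
    seeds = np.random.SeedSequence(seed).generate_state(len(panel))
    points: dict[str, list[tuple[float, float]]] = {}
    dynamics_truth: dict[str, str] = {}
    for i, ((gene, dose), tpl) in enumerate(sorted(panel.items())):
        ds = generate_dataset("planted", layout, templates=[tpl], noise=noise,
                              seed=int(seeds[i]))
        rec = ds.records
        basal = (rec[(rec["time_min"] <= 0) & (rec["barrier_count"] == 0)]
                 .groupby("cell_id")["intensity"].mean().mean())
        points.setdefault(gene, []).append(
            (population_steady(rec, windows) / basal,
             population_peak(rec, windows) / basal))
        dynamics_truth[gene] = tpl.dynamics
    gene_fits = {g: peak_vs_steady_regression(pts) for g, pts in points.items()}
    calls = split_pulsatile_gradual(gene_fits, threshold)
    class_slopes = {}
    for dyn in ("pulsatile", "gradual"):
        pts = np.array([p for g, pp in points.items()
                        if dynamics_truth[g] == dyn for p in pp])
        fit = linregress(pts[:, 0], pts[:, 1])
        class_slopes[dyn] = float(fit.slope)
    return {
        "class_slopes": class_slopes,
        "gene_slopes": {g: f.slope for g, f in gene_fits.items()},
        "split_counts": {
            "pulsatile": sum(c.dynamics == "pulsatile" for c in calls),
            "gradual": sum(c.dynamics == "gradual" for c in calls),
        },
        "split_correct": all(c.dynamics == dynamics_truth[c.gene] for c in calls),
        "n_points": {dyn: sum(dynamics_truth[g] == dyn for g in points) * len(doses)
                     for dyn in ("pulsatile", "gradual")},
    }


def reporter_panel_pulse(
    params: M.ModelParameters | None = None,
    concentration: float = 100.0,
    rise_horizon: float = 30.0,
) -> dict:
    """Mechanistic 31-reporter panel under a step treatment.

    Counts the reporters whose expression level exceeds their basal value
    within ``rise_horizon`` minutes (the growth-arrest-driven universal
    pulse) and measures the flatness of the constitutive control's
    reconstructed promoter activity.
    """
    params = params or M.ModelParameters()
    genes = M.reporter_panel(params) + [M.constitutive_gene(params)]
    traj = M.simulate(params, M.TreatmentProtocol.step(concentration), genes)
    t = traj.times
    risers = 0
    for gene in genes[:31]:
        s = traj.series(gene.name)
        basal = s[t <= 0].mean()
        if (s[(t > 0) & (t <= rise_horizon)] > basal).any():
            risers += 1
    const = traj.series("constitutive")
    activity = promoter_activity(t, traj.length_series(), const)
    baseline = float(np.nanmean(activity[t <= 0]))
    max_dev = float(np.nanmax(np.abs(activity[t > 0] - baseline)) / baseline)
    return {"n_reporters": 31, "n_risers": risers,
            "constitutive_activity_max_dev": max_dev}


def timing_recovery(
    seed: int,
    n_cells: int = 200,
    noise: NoiseModel | None = None,
) -> dict:
    """Recover single-cell time-to-peak for both dynamics classes.

    Plants ``n_cells`` mother-cell traces per class with peak times drawn
    from the published class distributions and measures them with
    :func:`~oxyregulon.metrics.cell_time_to_peak` (argmax within the 100-min
    horizon).
    """
    windows = AnalysisWindows()
    noise = noise or NoiseModel()
    seeds = np.random.SeedSequence(seed).generate_state(len(TIMING_CLASSES))
    out = {}
    for (cls, spec), s in zip(sorted(TIMING_CLASSES.items()), seeds):
        df = generate_timing_cells(
            n_cells, spec["mean"], spec["sd"], noise, seed=int(s),
            peak_width=spec["peak_width"])
        recovered = np.array([
            cell_time_to_peak(sub["time_min"].to_numpy(),
                              sub["intensity"].to_numpy(), windows)
            for _, sub in df.groupby("cell_id")])
        out[cls] = {
            "planted_mean": spec["mean"],
            "mean": float(recovered.mean()),
            "sd": float(recovered.std(ddof=1)),
            "se": float(recovered.std(ddof=1) / np.sqrt(n_cells)),
            "n": n_cells,
        }
    return out
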
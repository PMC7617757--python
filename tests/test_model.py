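"""Stress-model unit tests: growth inhibition, fixed points, protocols,
knockouts and the trench attenuation rule."""

import numpy as np
import pytest

from oxyregulon import (
    ConfigError,
    GeneSpec,
    ModelParameters,
    TreatmentProtocol,
    basal_steady_state,
    dose_response,
    growth_rate,
    knockout_katG,
    simulate,
    trench_profile,
)
from oxyregulon.model import (
    ModelState,
    constitutive_gene,
    derivatives,
    downregulated_reporter,
    reporter_panel,
)


# -- growth_rate ------------------------------------------------------------

def test_growth_rate_unstressed_is_g_max(params):
    assert growth_rate(0.0, params) == pytest.approx(params.g_max)


def test_growth_rate_half_inhibition_at_K_g(params):
    # Hill form: g(K_g) = g_max / 2 for any exponent
    assert growth_rate(params.K_g, params) == pytest.approx(params.g_max / 2)


def test_growth_rate_monotone_and_saturating(params):
    h = np.logspace(-6, 3, 200)
    g = growth_rate(h, params)
    assert np.all(np.diff(g) <= 0)
    assert g[-1] < 1e-6 * params.g_max


def test_growth_rate_rejects_negative(params):
    with pytest.raises(ValueError):
        growth_rate(-0.1, params)


def test_growth_coupling_toggle(params):
    p = params.replace(growth_coupling=False)
    assert growth_rate(50.0, p) == params.g_max


# -- derivatives ------------------------------------------------------------

def test_pure_dilution_when_oxyr_reduced(params):
    gene = GeneSpec("g", K_D=0.1, K_ind=5.0, R_basal=0.0)
    state = ModelState(OxyR_red=params.OxyR_total, GrxA=0.0, KatG=0.0, AhpC=0.0,
                       H2O2_cell=0.0, n=0.0, expr={"g": 3.0})
    d = derivatives(state, 0.0, params, [gene])
    assert d.expr["g"] == pytest.approx(-params.g_max * 3.0)


def test_occupancy_half_saturation(params):
    # oxidized OxyR equal to K_D -> induction at K_ind / 2
    gene = GeneSpec("g", K_D=0.5, K_ind=2.0, R_basal=0.0)
    state = ModelState(OxyR_red=params.OxyR_total - 0.5, GrxA=0.0, KatG=0.0,
                       AhpC=0.0, H2O2_cell=0.0, n=1.0, expr={"g": 0.0})
    d = derivatives(state, 0.0, params, [gene])
    assert d.expr["g"] == pytest.approx(1.0)


def test_constitutive_fixed_point(params):
    gene = constitutive_gene(params)
    level = params.R_constitutive / params.g_max
    state = ModelState(OxyR_red=params.OxyR_total, GrxA=0.0, KatG=0.0, AhpC=0.0,
                       H2O2_cell=0.0, n=0.0, expr={gene.name: level})
    d = derivatives(state, 0.0, params, [gene])
    assert d.expr[gene.name] == pytest.approx(0.0, abs=1e-12)


def test_downregulation_rate_clamped_at_zero(params):
    # strongly repressed plasmid gene: the production term floors at 0,
    # leaving pure dilution
    gene = GeneSpec("g", K_D=0.01, K_ind=-5.0, R_basal=1.0, on_plasmid=True)
    state = ModelState(OxyR_red=0.0, GrxA=0.0, KatG=0.0, AhpC=0.0,
                       H2O2_cell=0.0, n=10.0, expr={"g": 2.0})
    d = derivatives(state, 0.0, params, [gene])
    assert d.expr["g"] == pytest.approx(-params.g_max * 2.0)


def test_gene_spec_validation():
    with pytest.raises(ConfigError):
        GeneSpec("bad", K_D=-1.0, K_ind=0.0)
    with pytest.raises(ConfigError):
        GeneSpec("bad", K_D=0.2, K_ind=-30 * 0.2, R_basal=4.0)  # 4 - 6 < 0


# -- basal steady state -----------------------------------------------------

def test_basal_fixed_points(params):
    genes = [constitutive_gene(params),
             GeneSpec("inert", K_D=50.0, K_ind=0.05, R_basal=4.0)]
    state = basal_steady_state(params, genes)
    # plasmid copy number has no OxyR input: exact fixed point R_n / g_max
    assert state.n == pytest.approx(params.R_n / params.g_max, rel=1e-6)
    assert state.expr["constitutive"] == pytest.approx(
        params.R_constitutive / params.g_max, rel=1e-4)
    # negligible-occupancy reporter: R_basal / g_max within 1%
    assert state.expr["inert"] == pytest.approx(4.0 / params.g_max, rel=0.01)
    # conservation bound
    assert 0.0 <= state.OxyR_red <= params.OxyR_total
    # AhpC basal: R_ahpC_basal/g_max plus a small OxyR-dependent contribution
    assert state.AhpC == pytest.approx(params.R_ahpC_basal / params.g_max, rel=0.15)
    state.validate(params)


# -- simulate ---------------------------------------------------------------

def test_unperturbed_protocol_stays_at_basal(params):
    genes = [constitutive_gene(params),
             GeneSpec("inert", K_D=50.0, K_ind=0.05, R_basal=4.0)]
    traj = simulate(params, TreatmentProtocol.none(), genes, t_start=0.0, t_end=300.0)
    const = traj.series("constitutive")
    inert = traj.series("inert")
    assert np.allclose(const, params.R_constitutive / params.g_max, rtol=1e-3)
    assert np.allclose(inert, 4.0 / params.g_max, rtol=0.01)


def test_step_has_single_interior_h2o2_spike(params):
    traj = simulate(params, TreatmentProtocol.step(100.0), [])
    h = traj.series("H2O2_cell")
    post = traj.times > 0
    i_max = np.argmax(h)
    assert 0 < traj.times[i_max] < 60
    # a genuine transient: H2O2 decays to well below the spike and stays there
    assert np.all(h[i_max + 5:] < 0.5 * h[i_max])
    assert h[-1] < 0.5 * h[i_max]


def test_state_invariants_under_protocols(params):
    genes = [downregulated_reporter(), constitutive_gene(params)]
    for protocol in (TreatmentProtocol.step(100.0), TreatmentProtocol.graded()):
        traj = simulate(params, protocol, genes)
        assert np.all(traj.states >= 0)
        assert np.all(traj.series("OxyR_red") <= params.OxyR_total + 1e-9)


def test_simulate_argument_validation(params):
    with pytest.raises(ConfigError):
        simulate(params, TreatmentProtocol.none(), [], t_start=10, t_end=0)
    with pytest.raises(ConfigError):
        simulate(params, TreatmentProtocol.none(), [], dt_out=-1)


def test_protocol_validation():
    with pytest.raises(ConfigError):
        TreatmentProtocol(segments=((0.0, 10.0), (0.0, 20.0)))
    with pytest.raises(ConfigError):
        TreatmentProtocol(segments=((0.0, -5.0),))
    with pytest.raises(ConfigError):
        TreatmentProtocol(segments=((10.0, 5.0),))  # starts after t=0
    p = TreatmentProtocol.graded((25, 50, 100), (0, 60, 120))
    assert p.concentration_at(-1) == 0
    assert p.concentration_at(61) == 50


# -- dose response ----------------------------------------------------------

def test_dose_response_zero_dose_ratio_one(params):
    gene = GeneSpec("r", K_D=0.1, K_ind=3.0, R_basal=0.05)
    df = dose_response(params, gene, [0.0])
    assert df["peak_level"].iloc[0] / df["basal_level"].iloc[0] == pytest.approx(
        1.0, rel=1e-3)


def test_dose_response_monotone_peak_for_upregulated(params):
    gene = GeneSpec("r", K_D=0.1, K_ind=3.0, R_basal=0.05)
    df = dose_response(params, gene, [25.0, 50.0, 100.0])
    assert df["peak_level"].is_monotonic_increasing


def test_high_kd_has_steeper_activity_dose_slope(params):
    # equal K_ind / K_D; the high-K_D promoter's peak activity responds more
    # steeply to the external dose
    from scipy.stats import linregress

    hi = GeneSpec("hi", K_D=0.1, K_ind=3.0, R_basal=0.05)
    lo = GeneSpec("lo", K_D=0.01, K_ind=0.3, R_basal=0.05)
    doses = [25.0, 50.0, 100.0]
    slopes = {}
    for g in (hi, lo):
        df = dose_response(params, g, doses)
        slopes[g.name] = linregress(df["concentration"],
                                    df["peak_activity"] / df["basal_activity"]).slope
    assert slopes["hi"] > slopes["lo"]


def test_dose_response_refinement_oracle(params):
    gene = GeneSpec("r", K_D=0.05, K_ind=1.5, R_basal=0.05)
    coarse = dose_response(params, gene, [50.0])
    fine = dose_response(params, gene, [50.0], t_pre=120.0, t_post=360.0)
    # independent re-simulation on a finer output grid
    from oxyregulon.metrics import AnalysisWindows, trace_peak, trace_steady

    basal = basal_steady_state(params, [gene])
    traj = simulate(params, TreatmentProtocol.step(50.0), [gene],
                    t_start=-120, t_end=360, dt_out=1.5, initial_state=basal)
    w = AnalysisWindows()
    peak_fine = trace_peak(traj.times, traj.series("r"), w.peak_level)
    assert coarse["peak_level"].iloc[0] == pytest.approx(peak_fine, rel=0.01)
    assert coarse.equals(fine)


def test_dose_response_rejects_bad_doses(params):
    gene = GeneSpec("r", K_D=0.1, K_ind=1.0, R_basal=0.1)
    with pytest.raises(ConfigError):
        dose_response(params, gene, [-5.0])
    with pytest.raises(ConfigError):
        dose_response(params, gene, [25.0, 25.0])


# -- K_D ordering -----------------------------------------------------------

def test_peak_over_steady_monotone_in_kd(params):
    from oxyregulon.metrics import AnalysisWindows, trace_peak, trace_steady

    w = AnalysisWindows()
    ratios = []
    for kd in (0.01, 0.03, 0.06, 0.1):
        gene = GeneSpec("r", K_D=kd, K_ind=30 * kd, R_basal=0.05)
        traj = simulate(params, TreatmentProtocol.step(100.0), [gene])
        s = traj.series("r")
        ratios.append(trace_peak(traj.times, s, w.peak_level)
                      / trace_steady(traj.times, s, w.steady_level))
    assert np.all(np.diff(ratios) > 0)


# -- knockout ---------------------------------------------------------------

def test_knockout_is_idempotent_and_targeted(params):
    ko = knockout_katG(params)
    assert ko.Kind_KatG == 0.0 and ko.R_katG_basal == 0.0
    assert knockout_katG(ko) == ko
    assert ko.Kind_AhpC == params.Kind_AhpC
    assert ko.replace(Kind_KatG=params.Kind_KatG,
                      R_katG_basal=params.R_katG_basal) == params


def test_knockout_adapts_under_graded_dosing(params):
    ko = knockout_katG(params)
    traj = simulate(ko, TreatmentProtocol.graded(), [])
    assert traj.g_t[-1] > 0.5 * params.g_max


# -- plasmid ----------------------------------------------------------------

def test_plasmid_copy_number_transient_boost(params):
    traj = simulate(params, TreatmentProtocol.step(100.0), [])
    n = traj.series("n")
    basal = params.R_n / params.g_max
    peak = n.max()
    assert peak > 1.05 * basal  # growth arrest lifts the copy number
    # and it relaxes back toward the basal fixed point afterwards
    assert n[-1] - basal < 0.7 * (peak - basal)


def test_plasmid_reporter_gets_extra_boost(params):
    chrom = GeneSpec("chrom", K_D=0.02, K_ind=0.6, R_basal=0.05)
    plasm = GeneSpec("plasm", K_D=0.02, K_ind=0.6 / (params.R_n / params.g_max),
                     R_basal=0.05, on_plasmid=True)
    traj = simulate(params, TreatmentProtocol.step(100.0), [chrom, plasm])
    t = traj.times
    for name in ("chrom", "plasm"):
        pass
    c, p_ = traj.series("chrom"), traj.series("plasm")
    cb, pb = c[t <= 0].mean(), p_[t <= 0].mean()
    # same basal scale by construction; the plasmid reporter pulses higher
    assert pb == pytest.approx(cb, rel=0.05)
    assert (p_ / pb).max() > (c / cb).max()


# -- graded vs step ---------------------------------------------------------

def test_graded_spike_lower_than_step(params):
    step = simulate(params, TreatmentProtocol.step(100.0), [])
    graded = simulate(params, TreatmentProtocol.graded(), [])
    assert graded.series("H2O2_cell").max() < step.series("H2O2_cell").max()


# -- trench profile ---------------------------------------------------------

def test_trench_zero_attenuation_identical(params):
    gene = GeneSpec("r", K_D=0.05, K_ind=1.5, R_basal=0.05)
    trajs = trench_profile(params, [gene], n_positions=3, attenuation_per_cell=0.0)
    for traj in trajs[1:]:
        assert np.allclose(traj.series("r"), trajs[0].series("r"), rtol=1e-9)


def test_trench_attenuation_scales_dose(params):
    trajs = trench_profile(params, [], n_positions=3, attenuation_per_cell=0.3,
                           protocol=TreatmentProtocol.step(100.0))
    assert trajs[2].protocol.segments[0][1] == pytest.approx(49.0)


def test_pulsatile_reporter_decays_steeper_in_space(params):
    from oxyregulon.metrics import AnalysisWindows, trace_peak

    w = AnalysisWindows()
    hi = GeneSpec("hi", K_D=0.1, K_ind=3.0, R_basal=0.05)
    lo = GeneSpec("lo", K_D=0.01, K_ind=0.3, R_basal=0.05)
    trajs = trench_profile(params, [hi, lo], n_positions=3,
                           attenuation_per_cell=0.3)
    rel = {}
    for name in ("hi", "lo"):
        peaks = [trace_peak(tr.times, tr.series(name), w.peak_level)
                 for tr in trajs]
        rel[name] = peaks[2] / peaks[0]
    assert rel["hi"] < rel["lo"]


def test_trench_argument_validation(params):
    with pytest.raises(ConfigError):
        trench_profile(params, [], n_positions=0)
    with pytest.raises(ConfigError):
        trench_profile(params, [], n_positions=2, attenuation_per_cell=1.0)


# -- panel ------------------------------------------------------------------

def test_reporter_panel_composition(params):
    genes = reporter_panel(params)
    assert len(genes) == 31
    signs = [np.sign(g.K_ind) for g in genes]
    assert signs.count(1.0) == 13 and signs.count(-1.0) == 15 and signs.count(0.0) == 3
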
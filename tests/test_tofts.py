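"""Tofts forward model and fitting: analytic oracle, nesting, recovery."""

import numpy as np
import pandas as pd
import pytest

from lungdce.aif import AifSpec
from lungdce.conversion import concentration_to_signal
from lungdce.errors import InvalidInputError
from lungdce.synthetic import generate_phantom, render_dce
from lungdce.tofts import (
    ModelConfiguration,
    best_configuration,
    fit_curve,
    fit_voxelwise,
    r_squared,
    run_configuration_grid,
    tofts_forward,
)
from lungdce.types import Tcc, Tic


def weinmann_tm_closed_form(times, spec, ktrans, kep, t0):
    """Exact convolution of a bi-exponential plasma input with the Tofts
    impulse response: sum_i a_i D Ktrans (e^{-m_i tau} - e^{-Kep tau}) / (Kep - m_i)."""
    p = spec.params
    tau = np.clip(times - t0, 0.0, None)
    out = np.zeros_like(times, dtype=float)
    for a, m in ((p["a1"], p["m1"]), (p["a2"], p["m2"])):
        out += spec.dose * a * ktrans * (np.exp(-m * tau) - np.exp(-kep * tau)) / (kep - m)
    return np.where(times < t0, 0.0, out)


def test_zero_transfer_and_plasma_fraction_gives_zero_curve(georgiou):
    t = np.linspace(0, 5, 50)
    np.testing.assert_array_equal(tofts_forward(t, georgiou, 0.0, 1.0, 0.0, model="ETM"), 0.0)


def test_etm_with_zero_vp_equals_tm(georgiou):
    t = np.linspace(0, 5, 80)
    etm = tofts_forward(t, georgiou, 0.4, 1.5, 0.0, t0=0.1, model="ETM")
    tm = tofts_forward(t, georgiou, 0.4, 1.5, model="TM", t0=0.1)
    np.testing.assert_allclose(etm, tm, atol=1e-12)


def test_numerical_convolution_matches_biexponential_closed_form():
    spec = AifSpec("weinmann", t0=0.0)
    rng = np.random.default_rng(5)
    times = np.linspace(0, 10, 200)
    for _ in range(10):
        kt, kep, t0 = rng.uniform(0.01, 2), rng.uniform(0.05, 10), rng.uniform(0, 0.5)
        num = tofts_forward(times, spec, kt, kep, model="TM", t0=t0)
        ana = weinmann_tm_closed_form(times, spec, kt, kep, t0)
        assert np.max(np.abs(num - ana)) < 1e-4


def test_kep_must_be_positive(georgiou):
    with pytest.raises(InvalidInputError):
        tofts_forward(np.linspace(0, 2, 10), georgiou, 0.2, 0.0)


@pytest.mark.parametrize(
    "observed, fitted, expected",
    [
        ([0, 1, 2, 3], [0, 1, 2, 3], 1.0),
        ([0, 1, 2, 3], [1.5, 1.5, 1.5, 1.5], 0.0),  # mean predictor
        ([0, 1, 2, 3], [0, 1, 2, 5], 1.0 - 4.0 / 5.0),  # SS_res=4, SS_tot=5
    ],
)
def test_r_squared_hand_computed(observed, fitted, expected):
    assert r_squared(np.array(observed, float), np.array(fitted, float)) == pytest.approx(expected)


def test_r_squared_undefined_for_constant_observed():
    with pytest.raises(InvalidInputError):
        r_squared(np.full(5, 2.0), np.arange(5.0))


def test_fit_recovers_noiseless_parameters_to_high_precision(acq, georgiou):
    times = acq.frame_times_min()
    true = dict(ktrans=0.35, kep=1.4, vp=0.04, t0=0.13)
    curve = tofts_forward(times, georgiou, true["ktrans"], true["kep"], true["vp"],
                          t0=true["t0"], model="ETM")
    fit = fit_curve(Tcc(times=times, concentration=curve), "ETM", georgiou, t0_init=0.11)
    assert fit.converged
    for name in ("ktrans", "kep", "vp"):
        assert abs(getattr(fit, name) - true[name]) / true[name] < 1e-3
    assert abs(fit.t0_fit - true["t0"]) < 1e-4
    assert fit.r_squared > 0.9999
    assert fit.ve == pytest.approx(fit.ktrans / fit.kep)


def test_noise_only_curve_cannot_be_fit_well(acq, georgiou):
    """A zero-mean noise curve carries no kinetic signal: across draws the
    fitted R^2 stays near zero (and is frequently negative), far below the
    R^2 of genuinely enhancing curves."""
    times = acq.frame_times_min()
    rng = np.random.default_rng(17)
    r2s = []
    for _ in range(30):
        conc = rng.normal(0.0, 0.05, times.size)
        fit = fit_curve(Tcc(times=times, concentration=conc), "ETM", georgiou, t0_init=0.1)
        r2s.append(fit.r_squared)
    r2s = np.array(r2s)
    assert np.median(r2s) < 0.25
    assert np.mean(r2s <= 0) > 0.2


def test_degenerate_curve_returns_unconverged_result(georgiou):
    times = np.linspace(0, 2, 30)
    res = fit_curve(Tcc(times=times, concentration=np.zeros(30)), "ETM", georgiou, t0_init=0.1)
    assert not res.converged
    assert res.r_squared is None


def test_extended_model_nests_standard_model(acq, georgiou):
    """ETM can represent any TM curve, so its R^2 dominates; with a sizable
    true vascular fraction the TM fit is strictly worse."""
    times = acq.frame_times_min()
    curve = tofts_forward(times, georgiou, 0.25, 1.2, 0.05, t0=0.12, model="ETM")
    tcc = Tcc(times=times, concentration=curve)
    etm = fit_curve(tcc, "ETM", georgiou, t0_init=0.12)
    tm = fit_curve(tcc, "TM", georgiou, t0_init=0.12)
    assert etm.r_squared >= tm.r_squared - 1e-9
    assert tm.r_squared < etm.r_squared - 1e-4


def test_fit_insensitive_to_halving_internal_grid(acq, georgiou):
    times = acq.frame_times_min()
    rng = np.random.default_rng(3)
    curve = tofts_forward(times, georgiou, 0.3, 1.3, 0.02, t0=0.1, model="ETM")
    noisy = curve + rng.normal(0, 0.02, curve.shape)
    tcc = Tcc(times=times, concentration=noisy)
    coarse = fit_curve(tcc, "ETM", georgiou, t0_init=0.1, dt_fine=0.5)
    fine = fit_curve(tcc, "ETM", georgiou, t0_init=0.1, dt_fine=0.25)
    assert abs(fine.ktrans - coarse.ktrans) / coarse.ktrans < 0.005


def test_fit_is_deterministic(acq, georgiou):
    times = acq.frame_times_min()
    rng = np.random.default_rng(9)
    tcc = Tcc(times=times, concentration=tofts_forward(times, georgiou, 0.2, 1.0, 0.01, t0=0.1)
              + rng.normal(0, 0.02, times.size))
    a = fit_curve(tcc, "ETM", georgiou, t0_init=0.1)
    b = fit_curve(tcc, "ETM", georgiou, t0_init=0.1)
    assert (a.ktrans, a.kep, a.vp, a.t0_fit, a.r_squared) == (b.ktrans, b.kep, b.vp, b.t0_fit, b.r_squared)


@pytest.fixture(scope="module")
def noiseless_patient(acq, georgiou):
    phantom = generate_phantom((6, 6, 2), "hypo", np.random.default_rng(21),
                               t0_true=8.0 / 60.0, necrotic_fraction=0.0)
    series = render_dce(phantom, acq.with_(noise_sigma=0.0), georgiou, np.random.default_rng(22))
    return phantom, series


def test_voxelwise_fit_recovers_phantom_parameters(noiseless_patient):
    phantom, series = noiseless_patient
    maps = fit_voxelwise(series, phantom.tumor_mask, ModelConfiguration("ETM", "georgiou", "PG"))
    sel = phantom.tumor_mask
    for name, truth in (("ktrans", phantom.ktrans_map), ("kep", phantom.kep_map)):
        rel = np.abs(maps.maps[name][sel] - truth[sel]) / truth[sel]
        assert np.median(rel) < 0.01
    assert maps.meta["fraction_r2_nonpositive"] == 0.0


def test_voxelwise_fit_rejects_empty_mask(noiseless_patient):
    _, series = noiseless_patient
    with pytest.raises(InvalidInputError):
        fit_voxelwise(series, np.zeros(series.shape, dtype=bool),
                      ModelConfiguration("ETM", "georgiou", "PG"))


def test_necrotic_voxels_score_far_below_enhancing_voxels(acq, georgiou):
    """Non-enhancing (necrotic) voxels are baseline + noise; their fit
    quality clusters around zero while enhancing voxels fit near-perfectly,
    so the R^2 <= 0 exclusion removes necrosis preferentially."""
    phantom = generate_phantom((6, 6, 2), "hypo", np.random.default_rng(31),
                               t0_true=8.0 / 60.0, necrotic_fraction=0.3)
    series = render_dce(phantom, acq, georgiou, np.random.default_rng(32))
    maps = fit_voxelwise(series, phantom.tumor_mask, ModelConfiguration("ETM", "georgiou", "PG"))
    nec = maps.maps["r2"][phantom.necrotic_mask]
    enh = maps.maps["r2"][phantom.tumor_mask & ~phantom.necrotic_mask]
    assert np.median(enh) > 0.95
    assert np.median(nec) < 0.3
    assert np.mean(nec <= 0) > np.mean(enh <= 0)


def test_single_voxel_mask_yields_single_valued_maps(noiseless_patient):
    phantom, series = noiseless_patient
    mask = np.zeros(series.shape, dtype=bool)
    idx = tuple(np.argwhere(phantom.tumor_mask)[0])
    mask[idx] = True
    maps = fit_voxelwise(series, mask, ModelConfiguration("ETM", "georgiou", "PG"))
    assert np.sum(~np.isnan(maps.maps["ktrans"])) == 1


def test_configuration_grid_enumerates_18_cells():
    assert len(ModelConfiguration.all_configurations()) == 18
    labels = {c.label() for c in ModelConfiguration.all_configurations()}
    assert len(labels) == 18


def test_grid_on_single_patient_reports_that_patients_r2(noiseless_patient):
    phantom, series = noiseless_patient
    table = run_configuration_grid([(series, phantom.tumor_mask)])
    assert len(table) == 18
    best = table.loc[(table.model == "ETM") & (table.aif == "georgiou"), "median_r2"]
    assert best.max() > 0.999  # matching configuration reproduces the truth


def test_best_configuration_tie_breaks_toward_fewer_parameters():
    table = pd.DataFrame(
        [
            {"model": "ETM", "aif": "parker", "bat": "PG", "median_r2": 0.9},
            {"model": "TM", "aif": "weinmann", "bat": "LL", "median_r2": 0.9},
            {"model": "TM", "aif": "georgiou", "bat": "LQ", "median_r2": 0.9},
            {"model": "ETM", "aif": "georgiou", "bat": "PG", "median_r2": 0.5},
        ]
    )
    chosen = best_configuration(table)
    assert chosen.model == "TM"
    assert chosen.aif_name == "georgiou"  # lexicographic among remaining ties
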
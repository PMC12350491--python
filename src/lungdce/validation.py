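"""Self-validation experiments for the whole analysis chain.

Each function runs one seeded end-to-end experiment against an independent
reference — a closed-form convolution, an exact round-trip identity, the
simulator's ground truth, or a statistical null — and returns plain numbers.
They back both the validation test suite and the summary script; all sizes
are desk-scale by construction (small rendered volumes, tens of replicate
cohorts) and every random draw is a pure function of the seed.
"""

from __future__ import annotations

import numpy as np

from .aif import AifSpec
from .conversion import concentration_to_signal, signal_to_concentration
from .features import FEATURE_COLUMNS, build_feature_table
from .stats import kruskal_wallis, mann_whitney_u, roc_analysis
from .synthetic import (
    CohortConfig,
    EffectConfig,
    GroupEffect,
    default_acquisition,
    generate_cohort,
    generate_phantom,
    render_dce,
)
from .bat import estimate_bat_ll, estimate_bat_lq, estimate_bat_pg
from .tofts import (
    ModelConfiguration,
    best_configuration,
    fit_curve,
    fit_voxelwise,
    run_configuration_grid,
    tofts_forward,
    tofts_forward_many,
)
from .types import Tcc, Tic

__all__ = [
    "convolution_oracle_error",
    "signal_roundtrip_error",
    "parameter_recovery",
    "bat_hit_rates",
    "grid_self_consistency",
    "statistics_calibration",
    "stratification_rehearsal",
]

FAST_FRAME_MIN = 1.34 / 60.0


def biexponential_tofts_closed_form(times, spec: AifSpec, ktrans, kep, t0):
    """Analytic standard-Tofts curve for a bi-exponential plasma input."""
    p = spec.params
    tau = np.clip(times - t0, 0.0, None)
    out = np.zeros_like(times, dtype=float)
    for a, m in ((p["a1"], p["m1"]), (p["a2"], p["m2"])):
        out += spec.dose * a * ktrans * (np.exp(-m * tau) - np.exp(-kep * tau)) / (kep - m)
    return np.where(times < t0, 0.0, out)


def convolution_oracle_error(n_draws: int = 50, seed: int = 0) -> dict:
    """Max |numerical - closed form| tissue concentration over random kinetics."""
    spec = AifSpec("weinmann", t0=0.0)
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, 10.0, 200)
    worst = 0.0
    for _ in range(n_draws):
        kt = rng.uniform(0.01, 2.0)
        kep = rng.uniform(0.05, 10.0)
        t0 = rng.uniform(0.0, 0.5)
        num = tofts_forward(times, spec, kt, kep, model="TM", t0=t0)
        ana = biexponential_tofts_closed_form(times, spec, kt, kep, t0)
        worst = max(worst, float(np.max(np.abs(num - ana))))
    return {"max_abs_error_mM": worst, "n": n_draws}


def signal_roundtrip_error(n_curves: int = 1000, seed: int = 0) -> dict:
    """Max relative error of concentration -> signal -> concentration."""
    acq = default_acquisition()
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, 3.0, 30)
    worst = 0.0
    for _ in range(n_curves):
        conc = rng.uniform(0.0, 5.0, 30)
        conc[:3] = 0.0
        tic = concentration_to_signal(
            Tcc(times=times, concentration=conc), acq, s_baseline=rng.uniform(50.0, 500.0)
        )
        back = signal_to_concentration(tic, acq).concentration
        # relative error where concentration is nonzero; absolute (mM) at the
        # zero-concentration baseline frames, where relative error is undefined
        scale = np.where(conc != 0.0, np.abs(conc), 1.0)
        worst = max(worst, float(np.max(np.abs(back - conc) / scale)))
    return {"max_rel_error": worst, "n": n_curves}


def _recovery_once(n_voxels, noise_sigma, seed, aif_name="georgiou"):
    acq = default_acquisition(noise_sigma=noise_sigma)
    times = acq.frame_times_min()
    aif = AifSpec(aif_name)
    rng = np.random.default_rng(seed)
    kt = 0.25 * np.exp(rng.normal(0.0, 0.8, n_voxels))
    ve = np.clip(0.23 * np.exp(rng.normal(0.0, 0.3, n_voxels)), 1e-3, 1.0)
    kep = kt / ve
    vp = np.clip(0.0085 * np.exp(rng.normal(0.0, 0.8, n_voxels)), 0.0, 0.95)
    t0_true = 8.0 / 60.0
    curves = tofts_forward_many(times, aif, kt, kep, vp, t0=t0_true, model="ETM")
    s0 = 100.0
    err_kt, err_kep = [], []
    for i in range(n_voxels):
        tic = concentration_to_signal(Tcc(times=times, concentration=curves[i]), acq, s0)
        signal = tic.signal + rng.normal(0.0, noise_sigma * s0, times.size)
        tcc = signal_to_concentration(Tic(times=times, signal=signal, baseline_frames=6), acq)
        fit = fit_curve(tcc, "ETM", aif, t0_init=t0_true)
        err_kt.append(abs(fit.ktrans - kt[i]) / kt[i])
        err_kep.append(abs(fit.kep - kep[i]) / kep[i])
    return float(np.median(err_kt)), float(np.median(err_kep))


def parameter_recovery(n_voxels: int = 500, seed: int = 0) -> dict:
    """Median relative Ktrans/Kep error on simulated voxels at SNR 20, with
    the noise-free limit checked on a subset (errors must vanish)."""
    kt_snr20, kep_snr20 = _recovery_once(n_voxels, 0.05, seed)
    kt_low, kep_low = _recovery_once(100, 0.01, seed + 1)
    kt_zero, kep_zero = _recovery_once(100, 0.0, seed + 2)
    return {
        "ktrans_median_rel_error_snr20": kt_snr20,
        "kep_median_rel_error_snr20": kep_snr20,
        "ktrans_median_rel_error_snr100": kt_low,
        "kep_median_rel_error_snr100": kep_low,
        "ktrans_median_rel_error_noiseless": kt_zero,
        "kep_median_rel_error_noiseless": kep_zero,
        "n": n_voxels,
    }


def bat_hit_rates(n_reps: int = 200, seed: int = 0) -> dict:
    """Fraction of noisy replicates (SNR 20) where each estimator recovers the
    simulated bolus delay within one fast-frame spacing."""
    acq = default_acquisition(noise_sigma=0.05)
    aif = AifSpec("georgiou")
    rng = np.random.default_rng(seed)
    hits = {"LL": 0, "LQ": 0, "PG": 0}
    for rep in range(n_reps):
        t0_true = float(rng.uniform(4.0, 12.0)) / 60.0
        phantom = generate_phantom(
            (8, 8, 2), "hypo", np.random.default_rng(seed * 1000 + rep),
            t0_true=t0_true, necrotic_fraction=0.0,
        )
        series = render_dce(phantom, acq, aif, np.random.default_rng(seed * 1000 + rep + 1))
        tic = series.mean_tumor_tic(phantom.tumor_mask)
        for name, est in (("LL", estimate_bat_ll), ("LQ", estimate_bat_lq), ("PG", estimate_bat_pg)):
            if abs(est(tic).t0 - t0_true) <= FAST_FRAME_MIN + 1e-9:
                hits[name] += 1
    return {f"hit_rate_{k.lower()}": v / n_reps for k, v in hits.items()} | {"n": n_reps}


def homogeneous_etm_cohort_config() -> CohortConfig:
    """Noiseless cohort whose tumors are voxel-wise homogeneous ETM tissue:
    the mean-tumor curve is then itself an exact ETM curve, the condition
    under which fit self-consistency (R^2 -> 1) is well defined."""
    effect = EffectConfig(
        hypo=GroupEffect(0.25, 0.23, 0.02, sigma_voxel=(0.0, 0.0, 0.0)),
        hyper=GroupEffect(0.12, 0.20, 0.02, sigma_voxel=(0.0, 0.0, 0.0)),
        necrotic_fraction=0.0,
    )
    return CohortConfig(shape=(6, 6, 2), noise_sigma=0.0, effect=effect)


def grid_self_consistency(n_patients: int = 6, seed: int = 0) -> dict:
    """Run the 18-configuration grid on a noiseless homogeneous ETM cohort."""
    cohort = generate_cohort(n_patients, 1 / 3, seed=seed, config=homogeneous_etm_cohort_config())
    grid = run_configuration_grid(cohort)
    piv = grid.pivot_table(index=["aif", "bat"], columns="model", values="median_r2")
    margin = float((piv["ETM"] - piv["TM"]).min())
    best = best_configuration(grid)
    return {
        "n_configurations": int(len(grid)),
        "best_model": best.model,
        "best_median_r2": float(grid["median_r2"].max()),
        "min_etm_minus_tm_r2": margin,
        "n": n_patients,
    }


def statistics_calibration(seed: int = 0, n_null: int = 1000) -> dict:
    """Type-I error of the two nonparametric tests at alpha 0.05, and the
    exact U-statistic/AUC identity on tie-free data."""
    rng = np.random.default_rng(seed)
    mw_hits = kw_hits = 0
    for _ in range(n_null):
        x, y = rng.normal(size=20), rng.normal(size=20)
        if mann_whitney_u(x, y)[1] < 0.05:
            mw_hits += 1
        g = rng.normal(size=(3, 20))
        if kruskal_wallis(list(g))[1] < 0.05:
            kw_hits += 1
    max_identity_diff = 0.0
    for _ in range(100):
        n1, n2 = rng.integers(5, 15, 2)
        feature = np.concatenate([rng.normal(0.5, 1, n1), rng.normal(0, 1, n2)])
        labels = np.array(["pos"] * n1 + ["neg"] * n2)
        res = roc_analysis(feature, labels, n_boot=10, seed=int(rng.integers(1 << 16)))
        pos = feature[labels == res.positive_class]
        neg = feature[labels != res.positive_class]
        u, _ = mann_whitney_u(pos, neg)
        max_identity_diff = max(max_identity_diff, abs(res.auc - u / (len(pos) * len(neg))))
    return {
        "mw_type1_error_rate": mw_hits / n_null,
        "kw_type1_error_rate": kw_hits / n_null,
        "auc_u_identity_max_abs_diff": max_identity_diff,
        "n": n_null,
    }


def stratification_rehearsal(
    n_cohorts: int = 20,
    seed: int = 0,
    shape: tuple[int, int, int] = (8, 8, 3),
    n_shuffles: int = 40,
) -> dict:
    """End-to-end power check: replicate synthetic cohorts (38 patients,
    13 vs 25 at the 50% TPS split) through voxel-wise fitting and feature
    extraction; measure how often median Ktrans separates the groups, plus
    the false-positive rate under label shuffling."""
    config = ModelConfiguration("ETM", "georgiou", "PG")
    p_values, aucs = [], []
    first_features = first_labels = None
    for c in range(n_cohorts):
        cohort = generate_cohort(38, 13 / 38, seed=seed * 10_000 + c, config=CohortConfig(shape=shape))
        maps = {p.patient_id: fit_voxelwise(p.series, p.mask, config) for p in cohort.patients}
        feats = build_feature_table(maps)
        joined = feats.join(cohort.labels)
        ge = (joined["tps_percent"] >= 50).to_numpy()
        vals = joined["median_ktrans"].to_numpy(float)
        u, p = mann_whitney_u(vals[~ge], vals[ge])
        p_values.append(p)
        aucs.append(u / (np.sum(~ge) * np.sum(ge)))
        if c == 0:
            first_features, first_labels = feats, ge
    rng = np.random.default_rng(seed + 555)
    n_sig = n_tests = 0
    for _ in range(n_shuffles):
        perm = rng.permutation(first_labels)
        for col in FEATURE_COLUMNS:
            vals = first_features[col].to_numpy(float)
            ok = np.isfinite(vals)
            _, p = mann_whitney_u(vals[ok][~perm[ok]], vals[ok][perm[ok]])
            n_tests += 1
            n_sig += p < 0.05
    return {
        "frac_cohorts_p_below_005": float(np.mean(np.array(p_values) < 0.05)),
        "frac_cohorts_auc_above_07": float(np.mean(np.array(aucs) > 0.7)),
        "median_auc": float(np.median(aucs)),
        "median_p": float(np.median(p_values)),
        "shuffle_significant_rate": n_sig / n_tests,
        "n": n_cohorts,
    }
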
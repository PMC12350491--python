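"""Seeded synthetic DCE-MRI cohorts with known ground-truth pharmacokinetics.

The generator emulates a fast view-sharing (TWIST-like) lung acquisition: a
128-style matrix scaled down to a configurable shape, 30 frames on an
anisotropic time grid (a burst of ~1.34 s frames through the bolus followed
by ~10 s late frames), SPGR signal rendering, and additive Gaussian noise.
Tumors are ellipsoids whose voxel-wise (Ktrans, Ve, Vp) are drawn log-normal
around patient-level medians, which are themselves drawn log-normal around
group-level medians; Kep is derived as Ktrans / Ve.  The two groups mirror
the PD-L1 hypo-/hyper-expression contrast: the hypoexpression group is drawn
with higher Ktrans and Kep medians.

A fraction of tumor voxels is flagged necrotic and rendered as baseline plus
noise only, so they naturally fail the downstream fit-quality filter
(R^2 <= 0), exactly how non-enhancing tissue behaves in real lesions.

Everything is a pure function of (config, seed): identical inputs give
bitwise-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .aif import AifSpec
from .conversion import spgr_signal
from .errors import InvalidConfigError
from .tofts import tofts_forward_many
from .types import AcquisitionConfig, DceSeries, SEC_PER_MIN

__all__ = [
    "make_twist_timegrid",
    "GroupEffect",
    "EffectConfig",
    "GroundTruthPhantom",
    "generate_phantom",
    "render_dce",
    "CohortConfig",
    "PatientData",
    "SyntheticCohort",
    "generate_cohort",
    "write_cohort",
    "default_acquisition",
]


def make_twist_timegrid(
    n_frames: int = 30, fast_dt: float = 1.34, slow_dt: float = 10.0, n_fast: int = 25
) -> np.ndarray:
    """Anisotropic frame timestamps in seconds: one baseline frame at 0, then
    (n_fast - 1) frames at ``fast_dt`` spacing, remaining at ``slow_dt``."""
    if fast_dt <= 0 or slow_dt <= 0:
        raise InvalidConfigError("frame spacings must be positive")
    if fast_dt > slow_dt:
        raise InvalidConfigError("fast_dt must not exceed slow_dt")
    if not 1 <= n_fast <= n_frames:
        raise InvalidConfigError("need 1 <= n_fast <= n_frames")
    spacings = np.concatenate(
        [np.full(n_fast - 1, fast_dt), np.full(n_frames - n_fast, slow_dt)]
    )
    return np.concatenate([[0.0], np.cumsum(spacings)])


def default_acquisition(noise_sigma: float = 0.05, matrix_size=(128, 128, 30)) -> AcquisitionConfig:
    """TWIST-like defaults: TR 2.25 ms, flip 25 deg, 30 frames (25 fast at
    1.34 s, then 10 s), T10 = 1.4 s, r1 = 3.6 L/mmol/s (gadoterate, 1.5 T)."""
    return AcquisitionConfig(
        frame_times=make_twist_timegrid(),
        tr=2.25,
        flip_angle=25.0,
        t10=1.4,
        r1=3.6,
        noise_sigma=noise_sigma,
        matrix_size=matrix_size,
    )


@dataclass(frozen=True)
class GroupEffect:
    """Group-level parameter medians (min^-1 / fractions) and log-normal spreads."""

    ktrans_median: float
    ve_median: float
    vp_median: float
    sigma_patient: tuple[float, float, float] = (0.4, 0.15, 0.3)  # ktrans, ve, vp
    sigma_voxel: tuple[float, float, float] = (0.8, 0.3, 0.8)


@dataclass(frozen=True)
class EffectConfig:
    """Per-group effect sizes.  Defaults mirror the reported contrast between
    PD-L1 hypo- and hyper-expressing lung tumors: hypo Ktrans/Kep medians
    roughly double the hyper ones, Ve and Vp near-identical."""

    hypo: GroupEffect = GroupEffect(ktrans_median=0.25, ve_median=0.23, vp_median=0.0085)
    hyper: GroupEffect = GroupEffect(ktrans_median=0.12, ve_median=0.20, vp_median=0.0081)
    necrotic_fraction: float = 0.05

    def for_group(self, group: str) -> GroupEffect:
        if group not in ("hypo", "hyper"):
            raise InvalidConfigError("group must be 'hypo' or 'hyper'")
        return self.hypo if group == "hypo" else self.hyper

    def scaled_hypo_ktrans(self, factor: float) -> "EffectConfig":
        return replace(self, hypo=replace(self.hypo, ktrans_median=self.hypo.ktrans_median * factor))


@dataclass
class GroundTruthPhantom:
    """Known voxel-wise kinetics for one simulated lesion."""

    ktrans_map: np.ndarray  # min^-1
    kep_map: np.ndarray  # min^-1
    ve_map: np.ndarray  # fraction
    vp_map: np.ndarray  # fraction
    t0_true: float  # minutes
    necrotic_mask: np.ndarray
    tumor_mask: np.ndarray


def _ellipsoid_mask(shape: tuple[int, int, int], scale: float = 0.38) -> np.ndarray:
    center = (np.asarray(shape) - 1) / 2.0
    radii = np.maximum(np.asarray(shape) * scale, 1.0)
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    dist = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return dist <= 1.0


def generate_phantom(
    shape: tuple[int, int, int],
    group: str,
    seed,
    effect_config: EffectConfig | None = None,
    t0_true: float = 0.1,
    necrotic_fraction: float | None = None,
) -> GroundTruthPhantom:
    """Draw voxel-wise parameter maps for one patient of the given group.

    ``seed`` may be an integer or a numpy Generator.  Raw Ve draws above 1
    are clipped to 1 (with Kep rederived as Ktrans / Ve so the maps stay
    mutually consistent); a configuration whose draws exceed 1 in more than
    half the voxels is rejected as unphysical.
    """
    eff = (effect_config or EffectConfig()).for_group(group)
    if necrotic_fraction is None:
        necrotic_fraction = (effect_config or EffectConfig()).necrotic_fraction
    if not 0.0 <= necrotic_fraction < 1.0:
        raise InvalidConfigError("necrotic_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    tumor = _ellipsoid_mask(shape)
    n_vox = int(tumor.sum())

    # patient-level medians, then voxel-level draws around them
    medians = np.array([eff.ktrans_median, eff.ve_median, eff.vp_median])
    pat = medians * np.exp(rng.normal(0.0, eff.sigma_patient, 3))
    ktrans = pat[0] * np.exp(rng.normal(0.0, eff.sigma_voxel[0], n_vox))
    ve_raw = pat[1] * np.exp(rng.normal(0.0, eff.sigma_voxel[1], n_vox))
    vp = np.clip(pat[2] * np.exp(rng.normal(0.0, eff.sigma_voxel[2], n_vox)), 0.0, 0.95)
    if np.mean(ve_raw > 1.0) > 0.5:
        raise InvalidConfigError("effect config yields Ve > 1 in the majority of voxels")
    ve = np.clip(ve_raw, 1e-3, 1.0)
    kep = ktrans / ve

    maps = {}
    for name, vals in (("ktrans", ktrans), ("kep", kep), ("ve", ve), ("vp", vp)):
        m = np.zeros(shape)
        m[tumor] = vals
        maps[name] = m
    necrotic = np.zeros(shape, dtype=bool)
    n_necrotic = int(np.floor(necrotic_fraction * n_vox))
    if n_necrotic:
        flat_idx = np.flatnonzero(tumor)
        chosen = rng.choice(flat_idx, size=n_necrotic, replace=False)
        necrotic.flat[chosen] = True
    return GroundTruthPhantom(
        ktrans_map=maps["ktrans"],
        kep_map=maps["kep"],
        ve_map=maps["ve"],
        vp_map=maps["vp"],
        t0_true=t0_true,
        necrotic_mask=necrotic,
        tumor_mask=tumor,
    )


def render_dce(
    phantom: GroundTruthPhantom,
    acq: AcquisitionConfig,
    aif_spec: AifSpec,
    seed,
    s_baseline: float = 100.0,
    model: str = "ETM",
) -> DceSeries:
    """Render a noisy SPGR signal series from a ground-truth phantom.

    Enhancing voxels follow the (extended) Tofts forward model with the
    phantom's bolus delay; necrotic and background voxels stay at baseline.
    Noise is additive Gaussian with sigma = acq.noise_sigma * s_baseline.
    """
    shape = phantom.tumor_mask.shape
    times_min = acq.frame_times_min()
    conc = np.zeros(shape + (times_min.size,))
    enhancing = phantom.tumor_mask & ~phantom.necrotic_mask
    if enhancing.any():
        conc[enhancing] = tofts_forward_many(
            times_min,
            aif_spec,
            phantom.ktrans_map[enhancing],
            phantom.kep_map[enhancing],
            phantom.vp_map[enhancing],
            t0=phantom.t0_true,
            model=model,
        )
    r10 = 1.0 / acq.t10
    m0 = s_baseline / spgr_signal(r10, acq)
    signal = spgr_signal(r10 + acq.r1 * conc, acq, m0=m0)
    rng = np.random.default_rng(seed)
    if acq.noise_sigma > 0:
        signal = signal + rng.normal(0.0, acq.noise_sigma * s_baseline, signal.shape)
    return DceSeries(data=signal, acq=acq)


@dataclass(frozen=True)
class CohortConfig:
    """Simulation settings for a whole cohort.

    The rendered volume is kept small by default (the lesion, not the full
    thorax, is what the analysis consumes); the acquisition time grid and
    signal model are full-fidelity.
    """

    shape: tuple[int, int, int] = (12, 12, 3)
    effect: EffectConfig = field(default_factory=EffectConfig)
    noise_sigma: float = 0.05
    aif_name: str = "georgiou"
    model: str = "ETM"
    s_baseline: float = 100.0
    t0_range_s: tuple[float, float] = (4.0, 12.0)
    frac_tps_lt1_in_hypo: float = 13.0 / 25.0  # of hypo (<50%) patients, share below 1% TPS
    histology_probs: tuple[float, float, float] = (14 / 38, 12 / 38, 12 / 38)
    nodal_positive_prob: float = 34.0 / 38.0

    def acquisition(self) -> AcquisitionConfig:
        return default_acquisition(noise_sigma=self.noise_sigma, matrix_size=self.shape)


@dataclass
class PatientData:
    patient_id: str
    group: str  # 'hypo' (<50% TPS) or 'hyper' (>=50%)
    series: DceSeries
    mask: np.ndarray
    phantom: GroundTruthPhantom


@dataclass
class SyntheticCohort:
    patients: list[PatientData]
    labels: pd.DataFrame
    seed: int
    config: CohortConfig


_HISTOLOGIES = ("adeno", "squamous", "poorly_differentiated")


def generate_cohort(
    n_patients: int = 38,
    frac_hyper: float = 13.0 / 38.0,
    seed: int = 0,
    config: CohortConfig | None = None,
) -> SyntheticCohort:
    """Generate a labeled synthetic cohort with a controlled 50% TPS split.

    The default 38 patients with 13 hyper- and 25 hypo-expressors reproduces
    the group structure of the motivating clinical cohort; TPS values are a
    two-component mixture so both the 1% and 50% thresholds partition the
    cohort non-trivially.
    """
    config = config or CohortConfig()
    if n_patients < 2:
        raise InvalidConfigError("need at least 2 patients")
    if not 0.0 < frac_hyper < 1.0:
        raise InvalidConfigError("frac_hyper must lie in (0, 1)")
    n_hyper = int(round(n_patients * frac_hyper))
    n_hypo = n_patients - n_hyper
    if n_hyper < 1 or n_hypo < 1:
        raise InvalidConfigError("each TPS group needs at least 1 patient")

    ss = np.random.SeedSequence(seed)
    label_rng = np.random.default_rng(ss.spawn(1)[0])
    patient_seeds = ss.spawn(n_patients)
    acq = config.acquisition()
    aif = AifSpec(config.aif_name)

    groups = ["hyper"] * n_hyper + ["hypo"] * n_hypo
    n_lt1 = int(round(config.frac_tps_lt1_in_hypo * n_hypo))
    patients, rows = [], []
    hypo_seen = 0
    for i, group in enumerate(groups):
        pid = f"P{i + 1:03d}"
        child = patient_seeds[i].spawn(2)
        if group == "hyper":
            tps = float(label_rng.uniform(50.0, 100.0))
        else:
            hypo_seen += 1
            if hypo_seen <= n_lt1:
                tps = float(label_rng.uniform(0.0, 1.0))
            else:
                tps = float(label_rng.uniform(1.0, 50.0))
        histology = str(label_rng.choice(_HISTOLOGIES, p=config.histology_probs))
        nodal = "N1-N3" if label_rng.random() < config.nodal_positive_prob else "N0"
        t0_true = float(label_rng.uniform(*config.t0_range_s)) / SEC_PER_MIN
        phantom = generate_phantom(
            config.shape, group, np.random.default_rng(child[0]),
            effect_config=config.effect, t0_true=t0_true,
        )
        series = render_dce(
            phantom, acq, aif, np.random.default_rng(child[1]),
            s_baseline=config.s_baseline, model=config.model,
        )
        patients.append(
            PatientData(patient_id=pid, group=group, series=series,
                        mask=phantom.tumor_mask, phantom=phantom)
        )
        rows.append(
            {
                "patient_id": pid,
                "tps_percent": tps,
                "group_1pct": ">=1%" if tps >= 1.0 else "<1%",
                "group_50pct": ">=50%" if tps >= 50.0 else "<50%",
                "histology": histology,
                "nodal_status": nodal,
            }
        )
    labels = pd.DataFrame(rows).set_index("patient_id")
    return SyntheticCohort(patients=patients, labels=labels, seed=seed, config=config)


def write_cohort(cohort: SyntheticCohort, outdir) -> Path:
    """Write a cohort to disk: per-patient NIfTI volumes plus labels.csv and
    timegrid.csv (times in seconds, matching the on-disk convention)."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    for p in cohort.patients:
        pdir = outdir / p.patient_id
        pdir.mkdir(exist_ok=True)
        nib.save(nib.Nifti1Image(p.series.data.astype(np.float32), affine), pdir / "series.nii.gz")
        nib.save(nib.Nifti1Image(p.mask.astype(np.uint8), affine), pdir / "mask.nii.gz")
        nib.save(
            nib.Nifti1Image(p.phantom.necrotic_mask.astype(np.uint8), affine),
            pdir / "necrotic_mask.nii.gz",
        )
        for name in ("ktrans", "kep", "ve", "vp"):
            img = nib.Nifti1Image(getattr(p.phantom, f"{name}_map").astype(np.float32), affine)
            nib.save(img, pdir / f"truth_{name}.nii.gz")
    cohort.labels.to_csv(outdir / "labels.csv")
    acq = cohort.patients[0].series.acq
    pd.DataFrame({"frame_time_s": acq.frame_times}).to_csv(outdir / "timegrid.csv", index=False)
    return outdir
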
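# lungdce

Pharmacokinetic analysis of **temporally anisotropic lung DCE-MRI** for
imaging-biomarker studies — in particular, non-invasive stratification of
PD-L1 expression in non-small cell lung cancer.

Fast view-sharing (TWIST-like) DCE protocols trade uniform sampling for
speed: a burst of ~1.3 s frames through the contrast bolus followed by
sparse ~10 s frames. `lungdce` implements the full analysis chain for such
series and a synthetic-cohort generator with known ground truth, so every
stage is testable without patient data.

## The model

Tissue contrast concentration is described by the Tofts bicompartmental
models. The standard model (TM) is

$$C_t(t) = K^{trans} \int_0^t C_p(\tau;\,t_0)\, e^{-K_{ep}(t-\tau)}\, d\tau,$$

and the extended model (ETM) adds a vascular term $v_p\,C_p(t;\,t_0)$.
Here $K^{trans}$ (min⁻¹) is the plasma→interstitium transfer constant,
$K_{ep}$ (min⁻¹) the efflux rate, $v_e = K^{trans}/K_{ep}$ the interstitial
volume fraction, and $v_p$ the plasma volume fraction. $C_p$ is a population
arterial input function (Weinmann bi-exponential, Parker mixed
Gaussian+sigmoid, or a Georgiou-form gamma-variate sum), delay-corrected by
the bolus arrival time $t_0$, which is estimated from the mean-tumor signal
curve (LL / LQ / PG methods) and then refined as a free fit parameter.

The chain: SPGR signal → concentration inversion, bounded
trust-region-reflective least squares per voxel, an 18-cell
model × AIF × BAT configuration grid ranked by median R² of the mean-tumor
fit, first-order features (median / p90 / SD of each parameter map over
voxels with R² > 0), and the group statistics used in biomarker studies
(Mann–Whitney U, Kruskal–Wallis, ROC with Youden operating point and
bootstrap CI, Lin's CCC, covariate-adjusted logistic regression).

## Worked example

```bash
python examples/02_fit_mean_tumor_curve.py
```

```
estimated bolus arrival: 6.86 s (true 7.00 s)
fitted Ktrans = 0.169 min^-1 (tumor-mean truth 0.188)
fitted Kep    = 1.177 min^-1 (tumor-mean truth 1.047)
fitted Vp     = 0.0139; Ve = Ktrans/Kep = 0.144; R^2 = 0.9999
```

The peak-gradient estimator locates the bolus within a fraction of a fast
frame; the extended-Tofts fit of the mean-tumor curve explains essentially
all of the signal (R² ≈ 1) and its rate constants approximate the
tumor-average ground truth of the heterogeneous simulated lesion.

The other scripts in `examples/` cover cohort simulation
(`01_simulate_cohort.py`), configuration-grid model selection
(`03_configuration_grid.py`), the full PD-L1 stratification table
(`04_pdl1_stratification.py`), and inter-reader feature agreement via Lin's
CCC (`05_interreader_agreement.py`). A thin CLI mirrors the pipeline:

```bash
lungdce simulate --n-patients 38 --out cohort/
lungdce grid --cohort cohort/ --out grid.csv
lungdce run --out run/ --seed 0
```

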
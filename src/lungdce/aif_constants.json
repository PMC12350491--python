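{
  "_comment": "Population AIF parameter sets, version 1. Times in minutes, rates in 1/min, amplitudes chosen so the evaluated curve is in mM. 'weinmann' is published as a plasma concentration and is scaled by the injected dose (mmol/kg); 'parker' and 'georgiou' are whole-blood concentrations and are divided by (1 - hematocrit) at evaluation time. The georgiou entry is a gamma-variate bolus-pass + sigmoid-gated washout functional form with representative constants tuned to the qualitative features of high-temporal-resolution population AIFs (first-pass peak ~6 mM blood near 0.25 min with a 10-90% rise of ~7 s matching a 3-4 mL/s injection, recirculation shoulder, slowly decaying equilibrium tail); override via AifSpec(params=...) to use a site-specific calibration.",
  "version": 1,
  "weinmann": {
    "a1": 3.99,
    "a2": 4.78,
    "m1": 0.144,
    "m2": 0.0111
  },
  "parker": {
    "A1": 0.809,
    "A2": 0.33,
    "T1": 0.17046,
    "T2": 0.365,
    "sigma1": 0.0563,
    "sigma2": 0.132,
    "alpha": 1.05,
    "beta": 0.1685,
    "s": 38.078,
    "tau": 0.483
  },
  "georgiou": {
    "passes": [
      {"A": 2339.04, "alpha": 2.5, "tau": 0.1},
      {"A": 144000.0, "alpha": 7.0, "tau": 0.0786},
      {"A": 2523.6, "alpha": 7.0, "tau": 0.1286}
    ],
    "w_alpha": 1.0,
    "w_beta": 0.04,
    "w_s": 20.0,
    "w_tau": 0.6
  }
}
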
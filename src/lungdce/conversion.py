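"""Signal <-> concentration conversion via the SPGR steady-state equation.

The spoiled gradient-echo steady-state signal is

    S = M0 sin(a) (1 - E) / (1 - cos(a) E),   E = exp(-TR * R1)

with R1(t) = R1(0) + r1 * C(t), R1(0) = 1 / T10.  The full nonlinear model is
inverted rather than the linear low-concentration approximation: at the short
TR / large flip angle typical of fast view-sharing protocols the linear
approximation is poor at peak tumor concentrations.

The proportionality constant M0 sin(a) is fixed from the pre-bolus baseline
frames, so only the signal *ratio* to baseline matters.  Negative computed
concentrations from noise are retained (they keep residual statistics
unbiased); only samples outside the attainable signal range are clamped and
flagged in ``Tcc.clamped``.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidInputError
from .types import AcquisitionConfig, Tcc, Tic

__all__ = ["signal_to_concentration", "concentration_to_signal", "spgr_signal"]

# floor/ceiling on R1 (1/s) when the measured signal falls outside the range
# the SPGR model can produce; flagged per-frame in the output
_R1_MIN = 1e-6
_R1_MAX = 1e3


def spgr_signal(r1: np.ndarray, acq: AcquisitionConfig, m0: float = 1.0) -> np.ndarray:
    """SPGR steady-state signal for longitudinal rate r1 (1/s)."""
    tr_s = acq.tr / 1000.0
    a = np.deg2rad(acq.flip_angle)
    e = np.exp(-tr_s * np.asarray(r1, dtype=float))
    return m0 * np.sin(a) * (1 - e) / (1 - np.cos(a) * e)


def concentration_to_signal(tcc: Tcc, acq: AcquisitionConfig, s_baseline: float) -> Tic:
    """Forward-evaluate the SPGR signal for a concentration curve.

    ``s_baseline`` is the signal at zero concentration; M0 is derived from it
    so that ``C == 0`` maps exactly back to ``s_baseline``.
    """
    if s_baseline <= 0:
        raise InvalidInputError("s_baseline must be positive")
    r10 = 1.0 / acq.t10
    m0 = s_baseline / spgr_signal(r10, acq)
    r1 = r10 + acq.r1 * tcc.concentration
    signal = spgr_signal(r1, acq, m0=m0)
    return Tic(times=tcc.times, signal=signal, baseline_frames=1)


def signal_to_concentration(tic: Tic, acq: AcquisitionConfig) -> Tcc:
    """Invert the SPGR signal equation frame-by-frame into concentration (mM).

    The baseline constant is the mean of ``tic.baseline_frames`` pre-bolus
    frames.  Frames whose signal lies outside the model's attainable range
    are clamped to the nearest attainable R1 and flagged.
    """
    s0 = tic.baseline_mean()
    if s0 <= 0:
        raise InvalidInputError("mean baseline signal must be positive")
    tr_s = acq.tr / 1000.0
    a = np.deg2rad(acq.flip_angle)
    r10 = 1.0 / acq.t10
    e10 = np.exp(-tr_s * r10)
    # k = M0 sin(a), fixed from baseline
    k = s0 * (1 - np.cos(a) * e10) / (1 - e10)
    s = tic.signal
    # invert S = k (1-E)/(1-cos a E)  =>  E = (k - S) / (k - S cos a)
    denom = k - s * np.cos(a)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = (k - s) / denom
    e_lo = np.exp(-tr_s * _R1_MAX)
    e_hi = np.exp(-tr_s * _R1_MIN)
    bad = ~np.isfinite(e) | (e <= e_lo) | (e >= e_hi)
    e = np.clip(np.where(np.isfinite(e), e, e_hi), e_lo, e_hi)
    r1 = -np.log(e) / tr_s
    conc = (r1 - r10) / acq.r1
    return Tcc(times=tic.times, concentration=conc, clamped=bad)
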
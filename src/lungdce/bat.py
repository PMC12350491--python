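"""Bolus arrival time (BAT) estimation from a mean-tumor TIC.

Three automated estimators are provided, applied to the tumor-averaged
time-signal curve (not voxel-wise):

LL (linear-linear)
    Two-segment model: constant baseline joined continuously to a linear
    upslope at a candidate breakpoint frame; exhaustive least-squares search
    over breakpoints up to the global signal peak.
LQ (linear-quadratic)
    As LL, but the post-breakpoint segment is a quadratic that joins the
    baseline continuously (and with zero slope) at the breakpoint.  The fit
    window ends where the curve reaches a small fraction of its total rise
    (default 20%): a quadratic describes only the initial enhancement, and
    extending the window to the peak drags the breakpoint several seconds
    early on concave upslopes.
PG (peak-gradient)
    Locates the maximum temporal gradient of the (lightly smoothed) curve
    before the peak, walks back to the onset of that upslope (where the
    gradient first drops below a fixed fraction of the maximum), and by
    default refines the onset to sub-frame precision by linear interpolation
    of the gradient's threshold crossing.

LL, fitted over the whole baseline-to-peak window, carries a systematic lag
of one to two fast frames on tissue curves (the true onset is convex, not
piecewise-linear); LQ and PG localize the arrival to within one fast frame
under typical bolus-phase noise.

All gradients and segment fits use the actual frame timestamps, because the
acquisition grid is deliberately non-uniform (fast bolus-phase frames, sparse
late frames).  Estimates are invariant to affine rescaling of the signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, NoBolusError
from .types import Tic

__all__ = ["BatEstimate", "estimate_bat_ll", "estimate_bat_lq", "estimate_bat_pg", "estimate_bat"]

BAT_METHODS = ("LL", "LQ", "PG")


@dataclass
class BatEstimate:
    t0: float  # minutes
    method: str
    breakpoint_index: int
    diagnostics: dict


def _check_bolus(tic: Tic) -> int:
    """Return the global peak index, raising NoBolusError for flat curves.

    The noise floor is a robust estimate from successive differences; a curve
    whose total rise does not clear it carries no usable bolus.
    """
    s = tic.signal
    if not np.all(np.isfinite(s)):
        raise InvalidInputError("signal contains non-finite values")
    peak = int(np.argmax(s))
    sigma = 1.4826 * np.median(np.abs(np.diff(s))) / np.sqrt(2.0)
    floor = max(5.0 * sigma, 1e-12 + 1e-9 * float(np.max(np.abs(s))))
    if s[peak] - tic.baseline_mean() <= floor:
        raise NoBolusError("peak indistinct: no discernible bolus arrival")
    return peak


def _segment_fit(tic: Tic, quadratic: bool, method: str, window_fraction: float | None) -> BatEstimate:
    peak = _check_bolus(tic)
    if peak < 4:
        raise InvalidInputError(f"{method} needs >= 4 frames before the TIC peak")
    end = peak
    if window_fraction is not None:
        base = tic.baseline_mean()
        target = base + window_fraction * (tic.signal[peak] - base)
        end = int(np.argmax(tic.signal[: peak + 1] >= target))
        end = min(max(end, 4), peak)
    t = tic.times[: end + 1]
    s = tic.signal[: end + 1]
    peak = end
    best_k, best_sse, best_coef = -1, np.inf, None
    for k in range(1, peak):
        ramp = np.clip(t - t[k], 0.0, None)
        if quadratic:
            ramp = ramp**2
        design = np.column_stack([np.ones_like(t), ramp])
        coef, *_ = np.linalg.lstsq(design, s, rcond=None)
        if coef[1] < 0:  # upslope only; a downhill segment is no bolus onset
            coef = np.array([s.mean(), 0.0])
        resid = s - design @ coef
        sse = float(resid @ resid)
        # ties broken toward the earliest breakpoint
        if best_k < 0 or sse < best_sse - 1e-12 * (1.0 + best_sse):
            best_k, best_sse, best_coef = k, sse, coef
    return BatEstimate(
        t0=float(t[best_k]),
        method=method,
        breakpoint_index=best_k,
        diagnostics={"sse": best_sse, "baseline": float(best_coef[0]), "slope": float(best_coef[1])},
    )


def estimate_bat_ll(tic: Tic, window_fraction: float | None = None) -> BatEstimate:
    """Linear-linear breakpoint estimate of the bolus arrival time.

    The two-segment model (flat baseline, linear upslope) is fitted over
    [first frame, peak frame] by exhaustive breakpoint search; pass
    ``window_fraction`` to cap the window at that fraction of the total rise
    instead of the peak.
    """
    return _segment_fit(tic, quadratic=False, method="LL", window_fraction=window_fraction)


def estimate_bat_lq(tic: Tic, window_fraction: float | None = 0.2) -> BatEstimate:
    """Linear-quadratic breakpoint estimate of the bolus arrival time.

    The post-breakpoint segment is a quadratic joining the baseline with
    value and slope continuity; the fit window ends where the signal reaches
    ``window_fraction`` of its rise (None extends it to the peak frame).
    """
    return _segment_fit(tic, quadratic=True, method="LQ", window_fraction=window_fraction)


def _moving_average(s: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return s.astype(float)
    if window % 2 == 0:
        raise InvalidInputError("smoothing window must be odd")
    half = window // 2
    padded = np.concatenate([np.full(half, s[0]), s, np.full(half, s[-1])])
    return np.convolve(padded, np.ones(window) / window, mode="valid")


def estimate_bat_pg(
    tic: Tic,
    onset_fraction: float = 0.1,
    smoothing_window: int = 3,
    interpolate: bool = True,
) -> BatEstimate:
    """Peak-gradient estimate of the bolus arrival time.

    Parameters
    ----------
    onset_fraction
        Fraction of the maximum gradient defining the upslope onset.
    smoothing_window
        Odd moving-average width applied before differencing; 1 disables
        smoothing (useful for step-like noiseless inputs, where smoothing
        biases the onset one frame early).
    interpolate
        Refine the onset below frame resolution by linearly interpolating
        the gradient's crossing of the onset threshold; disable to return
        the onset frame time itself.
    """
    if not 0.0 < onset_fraction < 1.0:
        raise InvalidInputError("onset_fraction must lie in (0, 1)")
    if tic.times.size < 3:
        raise InvalidInputError("PG needs >= 3 frames")
    peak = _check_bolus(tic)
    if peak < 1:
        raise NoBolusError("signal peaks at the first frame; no upslope to locate")
    smooth = _moving_average(tic.signal, smoothing_window)
    # forward divided differences on the anisotropic grid: g[i] is the slope
    # of the segment starting at frame i
    grad = np.diff(smooth) / np.diff(tic.times)
    i_max = int(np.argmax(grad[:peak]))
    threshold = onset_fraction * grad[i_max]
    if threshold <= 0:
        raise NoBolusError("non-positive peak gradient before the TIC peak")
    onset = i_max
    while onset > 0 and grad[onset - 1] >= threshold:
        onset -= 1
    t0 = float(tic.times[onset])
    if interpolate and onset > 0 and grad[onset] > grad[onset - 1]:
        # sub-frame refinement: where the gradient crosses the threshold
        frac = (threshold - grad[onset - 1]) / (grad[onset] - grad[onset - 1])
        t0 = float(tic.times[onset - 1] + frac * (tic.times[onset] - tic.times[onset - 1]))
    return BatEstimate(
        t0=t0,
        method="PG",
        breakpoint_index=onset,
        diagnostics={"gradient": grad, "peak_gradient_index": i_max, "threshold": float(threshold)},
    )


def estimate_bat(tic: Tic, method: str, **kwargs) -> BatEstimate:
    """Dispatch to one of the three estimators by name (LL, LQ, PG)."""
    method = method.upper()
    if method == "LL":
        return estimate_bat_ll(tic)
    if method == "LQ":
        return estimate_bat_lq(tic)
    if method == "PG":
        return estimate_bat_pg(tic, **kwargs)
    raise InvalidInputError(f"unknown BAT method {method!r}; expected one of {BAT_METHODS}")
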
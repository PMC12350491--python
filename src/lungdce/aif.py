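"""Population arterial input functions (AIFs) with bolus-delay correction.

Three published functional forms are supported, each evaluated as a *plasma*
contrast concentration C_p(t) in mM on a time axis in minutes:

``weinmann``
    Bi-exponential plasma decay ``D * (a1 e^{-m1 t} + a2 e^{-m2 t})`` with the
    classic amplitude/rate constants (kg/L and min^-1) scaled by the injected
    dose D in mmol/kg.  Published directly as plasma concentration, so no
    hematocrit correction is applied.
``parker``
    Two Gaussian bolus passes plus a sigmoid-modulated exponential washout,
    published as a whole-blood concentration and divided by (1 - Hct) here.
``georgiou``
    A sum of gamma-variate bolus passes plus a sigmoid-gated exponential
    approach to the equilibrium tail, also whole-blood.  The shipped constants
    are representative (see ``aif_constants.json``) and overridable.

All forms are causal in the bolus delay t0: the curve is identically zero for
t < t0 and the published shape is evaluated at t - t0 afterwards.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from functools import lru_cache
from importlib import resources
from typing import Callable, Mapping

import numpy as np

from .errors import InvalidConfigError, UnsupportedAifError

__all__ = ["AifSpec", "evaluate_aif", "delay_correct", "load_default_params", "AIF_NAMES"]

AIF_NAMES = ("weinmann", "parker", "georgiou")

_REQUIRED = {
    "weinmann": {"a1", "a2", "m1", "m2"},
    "parker": {"A1", "A2", "T1", "T2", "sigma1", "sigma2", "alpha", "beta", "s", "tau"},
    "georgiou": {"passes", "w_alpha", "w_beta", "w_s", "w_tau"},
}


@lru_cache(maxsize=1)
def _load_constants() -> dict:
    text = resources.files("lungdce").joinpath("aif_constants.json").read_text()
    return json.loads(text)


def load_default_params(name: str) -> dict:
    """Load the shipped parameter set for one AIF from the versioned JSON file."""
    if name not in AIF_NAMES:
        raise UnsupportedAifError(f"unknown AIF {name!r}; expected one of {AIF_NAMES}")
    return dict(_load_constants()[name])


@dataclass(frozen=True)
class AifSpec:
    """A named population AIF with its parameters and bolus delay.

    Parameters
    ----------
    name
        One of ``weinmann``, ``parker``, ``georgiou``.
    params
        Parameter mapping for the functional form; ``None`` loads the shipped
        defaults.  Partial mappings are merged over the defaults.
    t0
        Bolus delay in minutes; the curve is exactly zero before t0.
    hematocrit
        Used to convert whole-blood forms (parker, georgiou) to plasma
        concentration via division by (1 - Hct).  Ignored for weinmann.
    dose
        Injected dose in mmol/kg; scales the weinmann amplitudes only.
    """

    name: str
    params: Mapping | None = None
    t0: float = 0.0
    hematocrit: float = 0.42
    dose: float = 0.1

    def __post_init__(self) -> None:
        if self.name not in AIF_NAMES:
            raise UnsupportedAifError(
                f"unknown AIF {self.name!r}; expected one of {AIF_NAMES}"
            )
        merged = load_default_params(self.name)
        if self.params is not None:
            merged.update(self.params)
        missing = _REQUIRED[self.name] - merged.keys()
        if missing:
            raise InvalidConfigError(f"AIF {self.name!r} missing parameters: {sorted(missing)}")
        object.__setattr__(self, "params", merged)
        if self.t0 < 0:
            raise InvalidConfigError("bolus delay t0 must be >= 0")
        if not 0.0 <= self.hematocrit < 1.0:
            raise InvalidConfigError("hematocrit must lie in [0, 1)")
        if self.dose <= 0:
            raise InvalidConfigError("dose must be positive")

    def with_t0(self, t0: float) -> "AifSpec":
        return replace(self, t0=t0)


def _weinmann(tau: np.ndarray, p: Mapping, dose: float) -> np.ndarray:
    return dose * (p["a1"] * np.exp(-p["m1"] * tau) + p["a2"] * np.exp(-p["m2"] * tau))


def _parker(tau: np.ndarray, p: Mapping) -> np.ndarray:
    g1 = p["A1"] / (p["sigma1"] * np.sqrt(2 * np.pi)) * np.exp(
        -((tau - p["T1"]) ** 2) / (2 * p["sigma1"] ** 2)
    )
    g2 = p["A2"] / (p["sigma2"] * np.sqrt(2 * np.pi)) * np.exp(
        -((tau - p["T2"]) ** 2) / (2 * p["sigma2"] ** 2)
    )
    washout = p["alpha"] * np.exp(-p["beta"] * tau) / (1 + np.exp(-p["s"] * (tau - p["tau"])))
    return g1 + g2 + washout


def _georgiou(tau: np.ndarray, p: Mapping) -> np.ndarray:
    # gamma variates A * t^alpha * exp(-t/tau) evaluated as exp(alpha log t - t/tau)
    # with a shared log; t = 0 contributes 0 (alpha > 0)
    pos = tau > 0
    log_tau = np.where(pos, np.log(np.where(pos, tau, 1.0)), 0.0)
    out = np.zeros_like(tau)
    for gv in p["passes"]:
        out += np.where(
            pos, gv["A"] * np.exp(gv["alpha"] * log_tau - tau / gv["tau"]), 0.0
        )
    out += p["w_alpha"] * np.exp(-p["w_beta"] * tau) / (
        1 + np.exp(-p["w_s"] * (tau - p["w_tau"]))
    )
    return out


def evaluate_aif(spec: AifSpec, times: np.ndarray) -> np.ndarray:
    """Evaluate the plasma concentration C_p(t) in mM at ``times`` (minutes).

    The curve is exactly zero for t < spec.t0.  Whole-blood forms are divided
    by (1 - hematocrit) to yield plasma concentration, as required by the
    Tofts models.
    """
    times = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(times)):
        raise InvalidConfigError("times must be finite")
    tau = times - spec.t0
    active = tau >= 0
    tau_pos = np.where(active, tau, 0.0)
    if spec.name == "weinmann":
        curve = _weinmann(tau_pos, spec.params, spec.dose)
    elif spec.name == "parker":
        curve = _parker(tau_pos, spec.params) / (1.0 - spec.hematocrit)
    else:
        curve = _georgiou(tau_pos, spec.params) / (1.0 - spec.hematocrit)
    return np.where(active, curve, 0.0)


def delay_correct(curve_fn: Callable[[np.ndarray], np.ndarray], t0: float):
    """Wrap a concentration-time function with a pure bolus-delay shift.

    Returns ``g`` with ``g(t) = curve_fn(t - t0)`` for t >= t0 and 0 before.
    """
    if t0 < 0:
        raise InvalidConfigError("delay t0 must be >= 0")

    def shifted(times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        tau = times - t0
        active = tau >= 0
        vals = np.asarray(curve_fn(np.where(active, tau, 0.0)), dtype=float)
        return np.where(active, vals, 0.0)

    return shifted
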
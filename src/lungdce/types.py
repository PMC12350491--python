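"""Core in-memory containers for DCE-MRI series and derived curves.

Unit conventions
----------------
Acquisition metadata is stored in acquisition units (frame times in seconds,
TR in milliseconds, T10 in seconds), matching how scanner protocols and files
report them.  Curve containers (:class:`Tic`, :class:`Tcc`) carry time in
minutes, because pharmacokinetic rate constants are min^-1 throughout; the
boundary conversion happens exactly once, in :meth:`DceSeries.times_min` /
:meth:`AcquisitionConfig.frame_times_min`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidConfigError, InvalidInputError

__all__ = ["AcquisitionConfig", "DceSeries", "Tic", "Tcc", "SEC_PER_MIN"]

SEC_PER_MIN = 60.0


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition parameters of a spoiled-gradient-echo DCE series.

    Parameters
    ----------
    frame_times
        Frame timestamps in **seconds**, strictly increasing, first frame at 0.
        The grid may be non-uniform (view-sharing sequences such as TWIST
        acquire a burst of fast frames followed by sparser late frames).
    tr
        Repetition time in **milliseconds**.
    flip_angle
        Excitation flip angle in degrees, in (0, 90).
    t10
        Pre-contrast tissue longitudinal relaxation time T1(0) in **seconds**.
    r1
        Longitudinal relaxivity of the contrast agent in L mmol^-1 s^-1.
    noise_sigma
        Additive Gaussian noise level as a fraction of the baseline signal
        (only used by the simulator).
    matrix_size
        Spatial matrix (nx, ny, nz); informational for real data, the
        rendering shape for simulated data.
    """

    frame_times: np.ndarray
    tr: float = 2.25
    flip_angle: float = 25.0
    t10: float = 1.4
    r1: float = 3.6
    noise_sigma: float = 0.05
    matrix_size: tuple[int, int, int] = (128, 128, 30)

    def __post_init__(self) -> None:
        times = np.asarray(self.frame_times, dtype=float)
        object.__setattr__(self, "frame_times", times)
        if times.ndim != 1 or times.size < 2:
            raise InvalidConfigError("frame_times must be a 1-D array with >= 2 frames")
        if times[0] != 0.0:
            raise InvalidConfigError("frame_times must start at 0")
        if np.any(np.diff(times) <= 0):
            raise InvalidConfigError("frame_times must be strictly increasing")
        if not np.all(np.isfinite(times)):
            raise InvalidConfigError("frame_times must be finite")
        if self.tr <= 0:
            raise InvalidConfigError("tr must be positive (milliseconds)")
        if not 0.0 < self.flip_angle < 90.0:
            raise InvalidConfigError("flip_angle must lie in (0, 90) degrees")
        if self.t10 <= 0 or self.r1 <= 0:
            raise InvalidConfigError("t10 and r1 must be positive")
        if self.noise_sigma < 0:
            raise InvalidConfigError("noise_sigma must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(self.frame_times.size)

    def frame_times_min(self) -> np.ndarray:
        """Frame timestamps in minutes (the unit used by the kinetic models)."""
        return self.frame_times / SEC_PER_MIN

    def with_(self, **kwargs) -> "AcquisitionConfig":
        return replace(self, **kwargs)


@dataclass
class DceSeries:
    """A 4-D DCE-MRI signal series (x, y, z, t) with its acquisition config."""

    data: np.ndarray
    acq: AcquisitionConfig

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise InvalidInputError("DceSeries.data must be 4-D (x, y, z, t)")
        if self.data.shape[3] != self.acq.n_frames:
            raise InvalidInputError(
                f"series has {self.data.shape[3]} frames but acquisition config "
                f"declares {self.acq.n_frames}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def times_min(self) -> np.ndarray:
        return self.acq.frame_times_min()

    def mean_tumor_tic(self, mask: np.ndarray, baseline_frames: int = 1) -> "Tic":
        """Average the signal over a boolean mask into a mean-tumor TIC."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.shape:
            raise InvalidInputError("mask shape does not match series")
        if not mask.any():
            raise InvalidInputError("mask is empty")
        signal = self.data[mask].mean(axis=0)
        return Tic(times=self.times_min(), signal=signal, baseline_frames=baseline_frames)

    def voxel_tic(self, index: tuple[int, int, int], baseline_frames: int = 1) -> "Tic":
        return Tic(
            times=self.times_min(),
            signal=self.data[index],
            baseline_frames=baseline_frames,
        )


@dataclass
class Tic:
    """A time-signal intensity curve: raw MR signal versus time (minutes)."""

    times: np.ndarray
    signal: np.ndarray
    baseline_frames: int = 1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape or self.times.ndim != 1:
            raise InvalidInputError("times and signal must be matching 1-D arrays")
        if self.baseline_frames < 1:
            raise InvalidInputError("baseline_frames must be >= 1")

    def baseline_mean(self) -> float:
        return float(self.signal[: self.baseline_frames].mean())


@dataclass
class Tcc:
    """A contrast-agent concentration curve (mM) versus time (minutes).

    ``clamped`` flags frames where the signal model could not be inverted and
    the concentration was clamped to the attainable range.
    """

    times: np.ndarray
    concentration: np.ndarray
    clamped: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.times.shape != self.concentration.shape or self.times.ndim != 1:
            raise InvalidInputError("times and concentration must be matching 1-D arrays")
        if self.clamped is None:
            self.clamped = np.zeros(self.times.shape, dtype=bool)
        else:
            self.clamped = np.asarray(self.clamped, dtype=bool)
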
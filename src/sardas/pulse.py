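"""Gaussian monocycle excitation pulse.

The ultra-wideband excitation is the first derivative of a Gaussian,

    S(t) = -A · (2π/τ) · (t - Tc) · exp(-½ · (2π (t - Tc) / τ)²),

with impulse width τ = 1/f0 tied to the center frequency f0 (5.8 GHz by
default, the ISM band the antenna radiates in) and time shift Tc. The pulse
is odd about Tc, has exactly two extrema at Tc ± τ/(2π), and its magnitude
spectrum peaks at f0. By default the leading constant A is chosen so the
peak amplitude is 1 (DAS images are invariant to a global pulse scale); a
``normalize=False`` flag reproduces the literal −e·(2π/τ) amplitude of the
source expression instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError

__all__ = [
    "PulseParams",
    "Waveform",
    "gaussian_monocycle",
    "evaluate_pulse",
    "default_time_axis",
    "spectral_peak_frequency",
]


@dataclass(frozen=True)
class PulseParams:
    """Parameters of the Gaussian monocycle.

    ``impulse_width`` defaults to 1/f0 when not overridden. ``amplitude_scale``
    multiplies whichever leading constant the ``normalize`` flag selects.
    """

    center_frequency: float = 5.8e9
    impulse_width: float | None = None
    time_shift: float = 0.5e-9
    amplitude_scale: float = 1.0
    normalize: bool = True

    def __post_init__(self) -> None:
        if not self.center_frequency > 0:
            raise InputError("center_frequency must be > 0")
        if self.impulse_width is not None and not self.impulse_width > 0:
            raise InputError("impulse_width must be > 0 when given")

    @property
    def tau(self) -> float:
        """Impulse width τ in seconds (1/f0 unless overridden)."""
        return self.impulse_width if self.impulse_width is not None else 1.0 / self.center_frequency


@dataclass(frozen=True)
class Waveform:
    """A sampled signal on a uniform, ascending time axis (seconds / volts)."""

    time: np.ndarray
    samples: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.samples, dtype=float)
        if t.ndim != 1 or t.shape != s.shape:
            raise InputError("time and samples must be 1-D arrays of equal length")
        _check_uniform(t)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "samples", s)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def to_text(self, path) -> None:
        """Write as two-column delimited text (time_s, amplitude)."""
        np.savetxt(path, np.column_stack([self.time, self.samples]), header="time_s amplitude")

    @classmethod
    def from_text(cls, path) -> "Waveform":
        data = np.loadtxt(path)
        return cls(time=data[:, 0], samples=data[:, 1])

    def to_hdf5(self, group) -> None:
        group.create_dataset("time_s", data=self.time)
        group.create_dataset("amplitude", data=self.samples)

    @classmethod
    def from_hdf5(cls, group) -> "Waveform":
        return cls(time=group["time_s"][:], samples=group["amplitude"][:])


def _check_uniform(t: np.ndarray, rtol: float = 1e-9) -> None:
    if t.size < 2:
        raise InputError("time axis needs at least two samples")
    dt = np.diff(t)
    if dt[0] <= 0 or not np.allclose(dt, dt[0], rtol=rtol, atol=0.0):
        raise InputError("time axis must be uniformly spaced and ascending")


def default_time_axis(n_samples: int = 512, t_max: float = 5e-9) -> np.ndarray:
    """Uniform grid over [0, t_max); default 512 samples over 0–5 ns."""
    return np.arange(n_samples) * (t_max / n_samples)


def evaluate_pulse(params: PulseParams, t) -> np.ndarray:
    """Closed-form monocycle evaluated at arbitrary times (vectorized).

    Used both to synthesize sampled waveforms and by the forward model to
    place delayed echo replicas exactly, without interpolation error.
    """
    t = np.asarray(t, dtype=float)
    tau = params.tau
    u = (t - params.time_shift) * (2.0 * math.pi / tau)
    if params.normalize:
        # Peak |S| of x·exp(-x²/2) is e^{-1/2} at x=1; scale so the peak is 1.
        amp = math.sqrt(math.e) * params.amplitude_scale
    else:
        amp = math.e * params.amplitude_scale
    return -amp * u * np.exp(-0.5 * u * u)


def gaussian_monocycle(params: PulseParams, time_axis) -> Waveform:
    """Sample the monocycle on a uniform time grid."""
    t = np.asarray(time_axis, dtype=float)
    _check_uniform(t)
    return Waveform(time=t, samples=evaluate_pulse(params, t))


def spectral_peak_frequency(waveform: Waveform) -> float:
    """Frequency (Hz) of the magnitude maximum of the waveform's DFT.

    Resolution is 1/(N·dt); use a long window for tight estimates.
    """
    spec = np.abs(np.fft.rfft(waveform.samples))
    freqs = np.fft.rfftfreq(waveform.samples.size, d=waveform.dt)
    return float(freqs[int(np.argmax(spec))])
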
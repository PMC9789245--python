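"""Charge-balanced biphasic stimuli and their DFT representation.

The Fourier FEM loop needs the stimulus twice: as a time series (for the QS
reference and for driving the neural model) and as a one-sided spectrum whose
bins drive one complex field solve each.  Conventions used throughout:

* window length equals ``1/df`` (default 1 ms at 1 kHz resolution),
* sampling rate ``1/dt`` is at least ``2*f_max`` (1 MHz for 500 kHz),
* the one-sided spectrum stores, per bin, a magnitude/phase pair such that
  ``x(t) = sum_k mag_k * cos(2*pi*f_k*t + phase_k)`` reconstructs the
  waveform exactly (DC and Nyquist carry no factor of two).

Synthesis of solver output reuses the same convention: a complex amplitude
``c_k`` per bin maps to ``sum_k Re(c_k * exp(j*2*pi*f_k*t))``, which is real
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StimulusWaveform",
    "StimulusSpectrum",
    "build_biphasic",
    "forward_dft",
    "inverse_dft",
    "LONG_STIMULUS",
    "SHORT_STIMULUS",
]

#: (phase_duration, phase_gap) of the two stimuli studied, in seconds.
LONG_STIMULUS = (200e-6, 40e-6)
SHORT_STIMULUS = (50e-6, 2e-6)


@dataclass(frozen=True)
class StimulusWaveform:
    """Current waveform on a uniform time grid (first sample at t = 0)."""

    samples: np.ndarray        # A
    dt: float                  # s
    onset: float               # s
    phase_duration: float      # s
    phase_gap: float           # s
    amplitude: float           # A

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dt

    @property
    def window(self) -> float:
        return len(self.samples) * self.dt

    @property
    def stim_end(self) -> float:
        """End time of the second (anodic) phase."""
        return self.onset + 2 * self.phase_duration + self.phase_gap

    def charge(self) -> float:
        return float(np.sum(self.samples) * self.dt)


def _divides(num: float, dt: float) -> bool:
    k = num / dt
    return abs(k - round(k)) < 1e-9


def build_biphasic(
    phase_duration: float,
    phase_gap: float,
    amplitude: float,
    dt: float = 1e-6,
    onset: float = 280e-6,
    window: float = 1e-3,
) -> StimulusWaveform:
    """Cathodic-phase-first charge-balanced biphasic current pulse.

    The first phase is negative (cathodic) at ``-amplitude``, followed by a
    zero gap and an anodic phase at ``+amplitude``.  All durations must be
    integer multiples of ``dt`` and the pulse must fit in the window.
    """
    if amplitude <= 0 or dt <= 0:
        raise ValueError("amplitude and dt must be positive")
    for name, d in [
        ("phase_duration", phase_duration),
        ("phase_gap", phase_gap),
        ("onset", onset),
        ("window", window),
    ]:
        if d < 0 or not _divides(d, dt):
            raise ValueError(f"{name} must be a non-negative multiple of dt")
    if onset + 2 * phase_duration + phase_gap > window + 1e-15:
        raise ValueError("stimulus does not fit in the window")
    n = round(window / dt)
    i0 = round(onset / dt)
    npd = round(phase_duration / dt)
    ngap = round(phase_gap / dt)
    samples = np.zeros(n)
    samples[i0 : i0 + npd] = -amplitude
    samples[i0 + npd + ngap : i0 + 2 * npd + ngap] = +amplitude
    return StimulusWaveform(samples, dt, onset, phase_duration, phase_gap, amplitude)


@dataclass(frozen=True)
class StimulusSpectrum:
    """One-sided DFT of a stimulus: bins at integer multiples of ``df``."""

    freqs: np.ndarray          # Hz, f_k = k*df including DC
    magnitude: np.ndarray      # A
    phase: np.ndarray          # rad
    df: float                  # Hz
    f_max: float               # Hz

    def __post_init__(self) -> None:
        k = self.freqs / self.df
        if not np.allclose(k, np.round(k), atol=1e-9):
            raise ValueError("bin frequencies must be integer multiples of df")
        if np.any(self.freqs > self.f_max * (1 + 1e-12)):
            raise ValueError("bin frequency above f_max")
        if len(self.freqs) != round(self.f_max / self.df) + 1:
            raise ValueError("bin count must be f_max/df + 1 (including DC)")

    @property
    def amplitudes(self) -> np.ndarray:
        """Complex bin amplitudes ``mag*exp(j*phase)`` (cosine convention)."""
        return self.magnitude * np.exp(1j * self.phase)


def forward_dft(w: StimulusWaveform, df: float = 1e3, f_max: float = 500e3) -> StimulusSpectrum:
    """One-sided DFT of a waveform with resolution ``df`` up to ``f_max``.

    Requires the window length to equal ``1/df`` and the sampling rate to be
    at least ``2*f_max``; with the defaults (1 ms window, 1 MHz sampling)
    this yields 501 bins from DC to the Nyquist frequency.
    """
    n = len(w.samples)
    if abs(w.window * df - 1.0) > 1e-9:
        raise ValueError("window length must equal 1/df")
    if 1.0 / w.dt < 2 * f_max * (1 - 1e-12):
        raise ValueError("sampling rate must be at least 2*f_max")
    n_bins = round(f_max / df) + 1
    spec = np.fft.rfft(w.samples)
    if n_bins > len(spec):
        raise ValueError("f_max exceeds the Nyquist frequency")
    c = spec[:n_bins] / n
    scale = np.full(n_bins, 2.0)
    scale[0] = 1.0
    if n % 2 == 0 and n_bins == n // 2 + 1:
        scale[-1] = 1.0  # Nyquist bin appears once in the full spectrum
    c = c * scale
    freqs = np.arange(n_bins) * df
    return StimulusSpectrum(freqs, np.abs(c), np.angle(c), df, f_max)


def inverse_dft(freqs, values, times) -> np.ndarray:
    """Synthesize a real time series from complex one-sided bin amplitudes.

    ``values`` may be 1-D (one series) or 2-D with shape (n_points, n_bins);
    the result has shape ``times`` or (n_points, len(times)).  Applying this
    to an unmodified spectrum reproduces the waveform at the sample times.
    """
    freqs = np.asarray(freqs, dtype=float)
    values = np.asarray(values, dtype=complex)
    times = np.asarray(times, dtype=float)
    if values.shape[-1] != len(freqs):
        raise ValueError("values and freqs length mismatch")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite spectrum values")
    phases = np.exp(1j * 2.0 * np.pi * np.outer(times, freqs))  # (nt, nf)
    if values.ndim == 1:
        return (phases @ values).real
    return (values @ phases.T).real


def reconstruct(spectrum: StimulusSpectrum, times) -> np.ndarray:
    """Inverse DFT of a stimulus spectrum at arbitrary times."""
    return inverse_dft(spectrum.freqs, spectrum.amplitudes, times)
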
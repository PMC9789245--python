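"""Lumped electrode-tissue interface and stimulation power limitation.

The implant electrode couples to tissue through a contact impedance

    Z_ET(f) = R_scar + 1 / (j * 2*pi*f * C_dl)

where ``C_dl`` is the double-layer (polarization) capacitance — areal
capacitance of the metal/electrolyte interface times the electrode surface —
and ``R_scar`` the series resistance of the fibrous encapsulation layer.
Because stimulation is current controlled, Z_ET does not change the tissue
potential V_M; it only raises the electrode terminal voltage
``V_E = V_M + Z_ET * I`` and with it the delivered power ``P = I * V_E``.

Safety electronics cap the instantaneous power at ``P_max`` (5 mW by
default).  The system is linear in the drive current, so limiting the worst
time step by ``I -> I*sqrt(P_max/max P)`` rescales every voltage in the model
by the same factor and pins the limited peak power exactly at the cap; this
single global scale keeps the stimulus shape-preserving and charge-balanced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "InterfaceModel",
    "cdl_from_radius",
    "z_et",
    "scar_resistance",
    "apply_power_limit",
    "DEFAULT_ADL",
    "DEFAULT_PMAX",
    "SCAR_SIGMA",
]

#: Mean areal double-layer capacitance of metal in aqueous solution, F/cm^2.
DEFAULT_ADL = 15e-6
#: Stimulation power cap, W.
DEFAULT_PMAX = 5e-3
#: Scar (encapsulation) tissue conductivity, S/m.
SCAR_SIGMA = 0.1


@dataclass(frozen=True)
class InterfaceModel:
    """Electrode-tissue interface parameters: C_dl (F), R_scar (ohm), P_max (W)."""

    c_dl: float
    r_scar: float = 0.0
    p_max: float = DEFAULT_PMAX

    def __post_init__(self) -> None:
        if self.c_dl <= 0:
            raise ValueError("C_dl must be positive")
        if self.r_scar < 0:
            raise ValueError("R_scar must be non-negative")
        if self.p_max <= 0:
            raise ValueError("P_max must be positive")


def cdl_from_radius(areal_cdl: float, radius: float) -> float:
    """Double-layer capacitance of a spherical electrode.

    ``areal_cdl`` is in F/cm^2, ``radius`` in meters; the areal value is
    multiplied by the sphere surface expressed in cm^2.
    """
    if areal_cdl <= 0 or radius <= 0:
        raise ValueError("areal capacitance and radius must be positive")
    area_cm2 = 4.0 * np.pi * (radius * 100.0) ** 2
    return areal_cdl * area_cm2


def scar_resistance(radius: float, thickness: float, sigma: float = SCAR_SIGMA) -> float:
    """Series resistance of a concentric scar shell around a spherical electrode.

    R = (1/(4*pi*sigma)) * (1/r1 - 1/r2) with r1 the electrode radius and
    r2 = r1 + thickness; zero thickness gives zero resistance.
    """
    if radius <= 0 or thickness < 0 or sigma <= 0:
        raise ValueError("invalid scar geometry")
    if thickness == 0:
        return 0.0
    return (1.0 / (4.0 * np.pi * sigma)) * (1.0 / radius - 1.0 / (radius + thickness))


def z_et(model: InterfaceModel, f):
    """Contact impedance ``R_scar + 1/(j*omega*C_dl)`` at frequency ``f`` Hz.

    The capacitor is an open circuit at DC; callers handling a DC bin should
    substitute ``R_scar`` alone (charge-balanced stimuli have essentially no
    DC content, so the sweep logs and skips that bin).
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("z_et is undefined at DC; handle the f=0 bin explicitly")
    out = model.r_scar + 1.0 / (1j * 2.0 * np.pi * f * model.c_dl)
    return complex(out) if out.ndim == 0 else out


def apply_power_limit(v_e: np.ndarray, current: np.ndarray, p_max: float = DEFAULT_PMAX):
    """Scale a stimulation episode so instantaneous power never exceeds ``p_max``.

    ``v_e`` and ``current`` are time series on a common grid.  Returns
    ``(scale, limited_v_e, limited_current)``; because the field problem is
    linear in the drive, both series scale by the same factor and the limited
    peak power equals ``p_max`` exactly when the cap binds.
    """
    v_e = np.asarray(v_e, dtype=float)
    current = np.asarray(current, dtype=float)
    if v_e.shape != current.shape:
        raise ValueError("series must share a time grid")
    if not (np.all(np.isfinite(v_e)) and np.all(np.isfinite(current))):
        raise ValueError("non-finite series")
    p_peak = float(np.max(current * v_e))
    if p_peak <= p_max:
        return 1.0, v_e, current
    scale = float(np.sqrt(p_max / p_peak))
    return scale, v_e * scale, current * scale
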
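"""Frequency-dependent dielectric properties of inner-ear tissues.

Biological tissue conducts (ionic conductivity ``sigma``) and stores charge
(relative permittivity ``eps_r``); both vary strongly with frequency.  The
combination relevant for time-harmonic volume-conductor problems is the
complex admittivity

    gamma(f) = sigma(f) + j * 2*pi*f * eps0 * eps_r(f)      [S/m]

The purely resistive ("quasi-static", QS) treatment is valid only where the
susceptivity-to-conductivity ratio ``omega*eps0*eps_r/sigma`` is much smaller
than one; this module exposes that ratio so callers can judge the QS
approximation per tissue and per frequency.

Dispersion is parameterized with the multi-term Cole-Cole model

    eps_hat(omega) = eps_inf + sum_k d_eps_k / (1 + (j*omega*tau_k)^(1-alpha_k))

whose real part is the permittivity and whose imaginary part contributes to
the measured conductivity on top of the ionic term.  Published four-term
parameter sets for cerebrospinal fluid, cortical bone and spinal-cord (nerve)
tissue are embedded as named constants; endolymph, perilymph and the saline
shell reuse the CSF values.

Nerve tissue is anisotropic: conductivity along the fiber axis (longitudinal)
exceeds the transversal one by roughly an order of magnitude.  The isotropic
spinal-cord curve is rescaled so that its 100 Hz conductivity matches the
desired longitudinal/transversal values, keeping the spectral shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "EPS0",
    "ColeColeParams",
    "TissueProperty",
    "AdmittivityTensor",
    "GABRIEL_COLE_COLE",
    "evaluate_cole_cole",
    "admittivity",
    "qs_ratio",
    "scale_nerve_conductivity",
    "property_bounds",
    "interp_property",
    "default_property",
    "constant_property",
]

#: Vacuum permittivity in F/m.
EPS0 = 8.854e-12


@dataclass(frozen=True)
class ColeColeParams:
    """Multi-term Cole-Cole dispersion parameters for one tissue.

    ``terms`` is a sequence of ``(delta_eps, tau, alpha)`` triples with
    ``tau`` in seconds and ``alpha`` in [0, 1); ``sigma_ionic`` is the static
    ionic conductivity in S/m.
    """

    eps_inf: float
    terms: tuple[tuple[float, float, float], ...]
    sigma_ionic: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.eps_inf) or self.eps_inf <= 0:
            raise ValueError("eps_inf must be finite and positive")
        if self.sigma_ionic < 0:
            raise ValueError("sigma_ionic must be non-negative")
        for d_eps, tau, alpha in self.terms:
            if d_eps < 0:
                raise ValueError("delta_eps must be non-negative")
            if tau <= 0:
                raise ValueError("tau must be positive")
            if not 0 <= alpha < 1:
                raise ValueError("alpha must lie in [0, 1)")


#: Four-term Cole-Cole parameterizations from the published dielectric
#: database (Gabriel et al.).  Keys are tissue names used by the phantom.
GABRIEL_COLE_COLE: dict[str, ColeColeParams] = {
    "cerebrospinal_fluid": ColeColeParams(
        eps_inf=4.0,
        terms=(
            (65.0, 7.958e-12, 0.10),
            (40.0, 1.592e-9, 0.0),
            (0.0, 159.155e-6, 0.20),
            (0.0, 15.915e-3, 0.0),
        ),
        sigma_ionic=2.0,
    ),
    "cortical_bone": ColeColeParams(
        eps_inf=2.5,
        terms=(
            (10.0, 13.263e-12, 0.20),
            (180.0, 79.577e-9, 0.20),
            (5.0e3, 159.155e-6, 0.20),
            (1.0e5, 15.915e-3, 0.0),
        ),
        sigma_ionic=0.020,
    ),
    # The dielectric database's "nerve" tissue was measured on spinal cord.
    "spinal_cord": ColeColeParams(
        eps_inf=4.0,
        terms=(
            (26.0, 7.958e-12, 0.10),
            (500.0, 106.103e-9, 0.15),
            (7.0e4, 15.915e-6, 0.20),
            (4.0e7, 15.915e-3, 0.0),
        ),
        sigma_ionic=0.006,
    ),
}


def evaluate_cole_cole(params: ColeColeParams, f):
    """Evaluate ``(sigma, eps_r)`` of a Cole-Cole parameter set at ``f`` Hz.

    The ionic conductivity enters ``sigma`` directly; the dispersion terms
    contribute their real part to ``eps_r`` and their (negative) imaginary
    part to ``sigma`` via ``-omega*eps0*Im``.  ``f`` may be a scalar or array
    and must be non-negative.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0) or not np.all(np.isfinite(f)):
        raise ValueError("frequency must be finite and non-negative")
    omega = 2.0 * np.pi * f
    disp = np.zeros(f.shape, dtype=complex)
    for d_eps, tau, alpha in params.terms:
        disp = disp + d_eps / (1.0 + (1j * omega * tau) ** (1.0 - alpha))
    eps_r = params.eps_inf + disp.real
    sigma = params.sigma_ionic - omega * EPS0 * disp.imag
    if f.ndim == 0:
        return float(sigma), float(eps_r)
    return sigma, eps_r


def admittivity(sigma, eps_r, f):
    """Complex admittivity ``sigma + j*2*pi*f*eps0*eps_r`` in S/m."""
    sigma = np.asarray(sigma, dtype=float)
    eps_r = np.asarray(eps_r, dtype=float)
    f = np.asarray(f, dtype=float)
    for name, a in (("sigma", sigma), ("eps_r", eps_r), ("f", f)):
        if not np.all(np.isfinite(a)):
            raise ValueError(f"{name} must be finite")
    if np.any(sigma <= 0) or np.any(eps_r < 0) or np.any(f < 0):
        raise ValueError("require sigma > 0, eps_r >= 0, f >= 0")
    out = sigma + 1j * 2.0 * np.pi * f * EPS0 * eps_r
    return complex(out) if out.ndim == 0 else out


def qs_ratio(sigma, eps_r, f):
    """Quasi-static validity ratio ``omega*eps0*eps_r/sigma`` (dimensionless)."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    out = 2.0 * np.pi * np.asarray(f, dtype=float) * EPS0 * np.asarray(eps_r, dtype=float) / sigma
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TissueProperty:
    """Tabulated ``sigma(f)`` and ``eps_r(f)`` for one tissue.

    Knot frequencies must be strictly increasing and all values positive;
    ``bound_tag`` distinguishes the default curve from the upper/lower
    uncertainty boundaries.
    """

    name: str
    freq_knots: np.ndarray
    sigma_knots: np.ndarray
    eps_knots: np.ndarray
    bound_tag: str = "default"

    def __post_init__(self) -> None:
        object.__setattr__(self, "freq_knots", np.asarray(self.freq_knots, dtype=float))
        object.__setattr__(self, "sigma_knots", np.asarray(self.sigma_knots, dtype=float))
        object.__setattr__(self, "eps_knots", np.asarray(self.eps_knots, dtype=float))
        if self.bound_tag not in ("default", "upper", "lower"):
            raise ValueError("bound_tag must be default/upper/lower")
        f = self.freq_knots
        if f.ndim != 1 or len(f) < 2 or np.any(np.diff(f) <= 0):
            raise ValueError("knot frequencies must be strictly increasing")
        if len(self.sigma_knots) != len(f) or len(self.eps_knots) != len(f):
            raise ValueError("knot arrays must have matching length")
        if np.any(self.sigma_knots <= 0) or np.any(self.eps_knots <= 0):
            raise ValueError("sigma and eps_r must be positive at every knot")

    def to_table(self, path) -> None:
        """Write knots as plain tabular text (frequency_Hz sigma_S_per_m eps_r)."""
        header = "frequency_Hz\tsigma_S_per_m\teps_r"
        data = np.column_stack([self.freq_knots, self.sigma_knots, self.eps_knots])
        np.savetxt(path, data, header=header, fmt="%.17g", delimiter="\t")

    @classmethod
    def from_table(cls, path, name: str, bound_tag: str = "default") -> "TissueProperty":
        data = np.atleast_2d(np.loadtxt(path))
        return cls(name, data[:, 0], data[:, 1], data[:, 2], bound_tag)


def default_property(
    tissue: str,
    f_min: float = 100.0,
    f_max: float = 500e3,
    knots_per_decade: int = 10,
) -> TissueProperty:
    """Tabulate an embedded Cole-Cole parameter set on a log-spaced knot grid.

    The canonical grid is 10 knots per decade between 100 Hz and 500 kHz,
    spanning the stimulus spectrum used by the Fourier FEM sweep.
    """
    params = GABRIEL_COLE_COLE[tissue]
    n = int(np.ceil(np.log10(f_max / f_min) * knots_per_decade)) + 1
    freqs = np.logspace(np.log10(f_min), np.log10(f_max), n)
    sigma, eps = evaluate_cole_cole(params, freqs)
    return TissueProperty(tissue, freqs, sigma, eps)


def constant_property(
    name: str,
    sigma: float,
    eps_r: float = 1e-30,
    f_min: float = 100.0,
    f_max: float = 500e3,
) -> TissueProperty:
    """Frequency-independent property table (QS-style tissue description)."""
    freqs = np.logspace(np.log10(f_min), np.log10(f_max), 8)
    return TissueProperty(
        name, freqs, np.full(8, float(sigma)), np.full(8, float(eps_r))
    )


def interp_property(prop: TissueProperty, f_query):
    """Cubic-spline interpolation of ``(sigma, eps_r)`` at ``f_query`` Hz.

    Splines are fit on (log10 f, log10 value) pairs because tissue properties
    span many decades; log-space interpolation cannot overshoot into
    non-physical negative values.  Queries outside the knot range raise.
    """
    f_query = np.asarray(f_query, dtype=float)
    fk = prop.freq_knots
    if np.any(f_query < fk[0] * (1 - 1e-12)) or np.any(f_query > fk[-1] * (1 + 1e-12)):
        raise ValueError(
            f"query outside knot range [{fk[0]:g}, {fk[-1]:g}] Hz; "
            "supply knots spanning the sweep"
        )
    lf = np.log10(fk)
    lq = np.log10(np.clip(f_query, fk[0], fk[-1]))
    sigma = 10.0 ** CubicSpline(lf, np.log10(prop.sigma_knots))(lq)
    eps = 10.0 ** CubicSpline(lf, np.log10(prop.eps_knots))(lq)
    if f_query.ndim == 0:
        return float(sigma), float(eps)
    return sigma, eps


def scale_nerve_conductivity(base: TissueProperty, target_sigma_100hz: float) -> TissueProperty:
    """Rescale a nerve conductivity curve to a directional 100 Hz value.

    The isotropic spinal-cord curve serves as the spectral template; all
    conductivity knots are multiplied by ``target / sigma_base(100 Hz)`` so
    the curve passes through the longitudinal or transversal low-frequency
    conductivity.  Permittivity knots are left unchanged: no directional
    permittivity measurements exist to scale against, so the isotropic values
    are retained for both directions.
    """
    if target_sigma_100hz <= 0:
        raise ValueError("target conductivity must be positive")
    sigma_100, _ = interp_property(base, 100.0)
    k = target_sigma_100hz / sigma_100
    return replace(base, sigma_knots=base.sigma_knots * k)


def property_bounds(
    default: TissueProperty,
    mode: str,
    literature: TissueProperty | None = None,
    fraction: float = 0.5,
) -> tuple[TissueProperty, TissueProperty]:
    """Lower/upper uncertainty boundaries for a tissue property table.

    ``fractional`` scales every knot by ``1 -/+ fraction`` (used for nerve
    tissue, +-50 % by default).  ``median_log_distance`` measures the median
    absolute log10 distance between the default curve and independent
    literature values (separately for sigma and eps_r) and places the bounds
    at ``default * 10^(+-d)`` (used for bone and CSF).
    """
    if mode == "fractional":
        if not 0 < fraction < 1:
            raise ValueError("fraction must lie in (0, 1)")
        lo = replace(
            default,
            sigma_knots=default.sigma_knots * (1 - fraction),
            eps_knots=default.eps_knots * (1 - fraction),
            bound_tag="lower",
        )
        hi = replace(
            default,
            sigma_knots=default.sigma_knots * (1 + fraction),
            eps_knots=default.eps_knots * (1 + fraction),
            bound_tag="upper",
        )
        return lo, hi
    if mode == "median_log_distance":
        if literature is None:
            raise ValueError("median_log_distance mode requires literature values")
        # literature knots must cover the default knots
        try:
            lit_sigma, lit_eps = interp_property(literature, default.freq_knots)
        except ValueError as exc:
            raise ValueError("literature values do not cover the default knots") from exc
        d_sigma = np.median(np.abs(np.log10(lit_sigma) - np.log10(default.sigma_knots)))
        d_eps = np.median(np.abs(np.log10(lit_eps) - np.log10(default.eps_knots)))
        lo = replace(
            default,
            sigma_knots=default.sigma_knots * 10.0 ** (-d_sigma),
            eps_knots=default.eps_knots * 10.0 ** (-d_eps),
            bound_tag="lower",
        )
        hi = replace(
            default,
            sigma_knots=default.sigma_knots * 10.0 ** (+d_sigma),
            eps_knots=default.eps_knots * 10.0 ** (+d_eps),
            bound_tag="upper",
        )
        return lo, hi
    raise ValueError(f"unknown bounds mode {mode!r}")


@dataclass(frozen=True)
class AdmittivityTensor:
    """3x3 complex admittivity tensor in S/m.

    Isotropic regions use ``gamma * I``; nerve regions use distinct
    longitudinal/transversal eigenvalues with the longitudinal axis aligned
    to the local fiber direction.  The real part must be symmetric positive
    definite and the imaginary part symmetric positive semi-definite.
    """

    value: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.value, dtype=complex)
        object.__setattr__(self, "value", v)
        if v.shape != (3, 3):
            raise ValueError("tensor must be 3x3")
        if not np.allclose(v, v.T):
            raise ValueError("tensor must be symmetric")
        re_eig = np.linalg.eigvalsh(v.real)
        im_eig = np.linalg.eigvalsh(v.imag)
        if np.any(re_eig <= 0):
            raise ValueError("real part must be positive definite")
        if np.any(im_eig < -1e-18 * max(1.0, abs(im_eig).max())):
            raise ValueError("imaginary part must be positive semi-definite")

    @classmethod
    def isotropic(cls, gamma: complex) -> "AdmittivityTensor":
        return cls(np.eye(3) * gamma)

    @classmethod
    def uniaxial(cls, gamma_l: complex, gamma_t: complex, axis) -> "AdmittivityTensor":
        a = np.asarray(axis, dtype=float)
        norm = np.linalg.norm(a)
        if norm == 0:
            raise ValueError("fiber axis must be non-zero")
        a = a / norm
        return cls(gamma_t * np.eye(3) + (gamma_l - gamma_t) * np.outer(a, a))
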
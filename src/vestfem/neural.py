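"""SENN myelinated-fiber model driven by extracellular potentials.

Each node of Ranvier is an excitable patch (voltage-gated Na+ and K+
channels with Frankenhaeuser-Huxley-type rate equations, a leak, and a
membrane capacitance); consecutive nodes couple through the axoplasmic
conductance of the myelinated internode.  The extracellular potential Ve at
the nodes enters through the cable term, so a spatially uniform Ve produces
no drive (the classical activating-function null space) and scaling the
field scales the whole problem linearly.

Per-node quantities derive from the fiber outer diameter D: axon diameter
0.7*D, nodal gap 2.5 um, internode length 100*D, axoplasmic resistivity
1.1 ohm*m.  Specific membrane constants (2 uF/cm^2; 1445, 40 and
30.3 mS/cm^2 for Na, K and leak) and the FH rate functions are stored in a
documented kinetics config; rates are Q10-corrected from their 20 degC
reference to body temperature.  The leak reversal is chosen so the resting
state is an exact fixed point of the discretized dynamics.

Integration: implicit (backward-Euler) update of the cable system with the
ionic term linearized around the freshly updated gating state (chord
conductance), and exact exponential (Rush-Larsen) gating updates.  This
keeps gating variables in [0, 1] and tolerates the stiff nodal dynamics at
the default dt of 1 us.

A fiber counts as activated when the Na+ activation parameter m exceeds 0.7
at any node; thresholds are found by bisection on the stimulus amplitude,
terminating when the bracket width falls below 0.1 % of its upper end
(the upper, activating, bound is reported).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import FiberGeometry

__all__ = [
    "FhKinetics",
    "MembraneParams",
    "ThresholdResult",
    "extracellular_at_nodes",
    "simulate_fiber",
    "simulate_fibers",
    "find_threshold",
    "find_thresholds",
]


def _vtrap(x, y):
    """x / (1 - exp(-x/y)) with the removable singularity at x = 0 filled."""
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        out = x / (1.0 - np.exp(-x / y))
    small = np.abs(x) < 1e-7
    return np.where(small, y + 0.5 * x, out)


@dataclass(frozen=True)
class FhKinetics:
    """FH-type gating rates (1/ms as functions of mV above rest) with Q10s."""

    temperature: float = 310.15        # K
    t_ref: float = 293.15              # K, reference of the rate constants
    q10_m: float = 1.8
    q10_h: float = 2.8
    q10_n: float = 3.2

    def _q(self, q10: float) -> float:
        return q10 ** ((self.temperature - self.t_ref) / 10.0)

    def rates(self, v_mv):
        """alpha/beta for m, h, n in 1/s at relative membrane voltage v_mv."""
        qm, qh, qn = self._q(self.q10_m), self._q(self.q10_h), self._q(self.q10_n)
        am = 0.36 * _vtrap(v_mv - 22.0, 3.0) * qm
        bm = 0.40 * _vtrap(13.0 - v_mv, 20.0) * qm
        ah = 0.10 * _vtrap(-10.0 - v_mv, 6.0) * qh
        bh = 4.5 / (1.0 + np.exp((45.0 - v_mv) / 10.0)) * qh
        an = 0.02 * _vtrap(v_mv - 35.0, 10.0) * qn
        bn = 0.05 * _vtrap(10.0 - v_mv, 10.0) * qn
        return tuple(1e3 * np.asarray(r) for r in (am, bm, ah, bh, an, bn))

    def steady_state(self):
        am, bm, ah, bh, an, bn = self.rates(0.0)
        return am / (am + bm), ah / (ah + bh), an / (an + bn)


# specific membrane constants (per cm^2) and geometry scalings
_CM_SPEC = 2e-6          # F/cm^2
_GNA_SPEC = 1445e-3      # S/cm^2
_GK_SPEC = 40e-3         # S/cm^2
_GL_SPEC = 30.3e-3       # S/cm^2
_E_NA = 115e-3           # V above rest
_E_K = -33e-3            # V above rest
_NODE_GAP = 2.5e-6       # m
_AXON_RATIO = 0.7        # axon / fiber outer diameter
_RHO_AXIAL = 1.1         # ohm*m


@dataclass(frozen=True)
class MembraneParams:
    """Per-node SENN parameters of one fiber."""

    c_m: float                 # F per node
    g_na_max: float            # S per node
    g_k_max: float             # S per node
    g_leak: float              # S per node
    e_na: float                # V above rest
    e_k: float                 # V above rest
    e_leak: float              # V above rest (set for resting equilibrium)
    g_axial: float             # S between adjacent nodes
    v_rest: float = -70e-3     # V absolute
    kinetics: FhKinetics = FhKinetics()

    def __post_init__(self) -> None:
        for name in ("c_m", "g_na_max", "g_k_max", "g_leak", "g_axial"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def for_fiber(
        cls, fiber_or_diameter, kinetics: FhKinetics | None = None
    ) -> "MembraneParams":
        """Derive per-node values from a fiber's outer diameter."""
        kin = kinetics or FhKinetics()
        if isinstance(fiber_or_diameter, FiberGeometry):
            d_outer = fiber_or_diameter.diameter
            internode = fiber_or_diameter.internode_length
        else:
            d_outer = float(fiber_or_diameter)
            internode = 100.0 * d_outer
        d_axon = _AXON_RATIO * d_outer
        area_cm2 = np.pi * d_axon * _NODE_GAP * 1e4     # m^2 -> cm^2
        g_na = _GNA_SPEC * area_cm2
        g_k = _GK_SPEC * area_cm2
        g_l = _GL_SPEC * area_cm2
        m0, h0, n0 = kin.steady_state()
        # leak reversal that makes rest an exact equilibrium:
        # g_na*m0^2*h0*(0 - e_na) + g_k*n0^2*(0 - e_k) + g_l*(0 - e_leak) = 0
        e_leak = -(g_na * m0**2 * h0 * _E_NA + g_k * n0**2 * _E_K) / g_l
        g_axial = np.pi * d_axon**2 / (4.0 * _RHO_AXIAL * internode)
        return cls(
            c_m=_CM_SPEC * area_cm2,
            g_na_max=g_na,
            g_k_max=g_k,
            g_leak=g_l,
            e_na=_E_NA,
            e_k=_E_K,
            e_leak=e_leak,
            g_axial=g_axial,
            kinetics=kin,
        )


@dataclass(frozen=True)
class ThresholdResult:
    fiber_id: int
    threshold_amplitude: float     # A
    converged: bool
    iterations: int


def extracellular_at_nodes(field_solution, fibers, times, current_samples=None):
    """Extracellular potential time series at every node of every fiber.

    ``field_solution`` is either a :class:`~vestfem.field_solver.QsSolution`
    (requires ``current_samples``, the stimulus current at ``times``) or a
    :class:`~vestfem.field_solver.FourierSweep`.  Node potentials come from
    barycentric (P1) interpolation inside the containing tetrahedron and,
    for the Fourier case, inverse-DFT synthesis.  Returns an array of shape
    (n_fibers, n_nodes, n_times); raises if a node lies outside the mesh.
    """
    single = isinstance(fibers, FiberGeometry)
    fib_list = [fibers] if single else list(fibers)
    nodes = np.vstack([f.node_positions for f in fib_list])
    n_nodes = len(fib_list[0].node_positions)
    if hasattr(field_solution, "synthesize_phi"):          # FourierSweep
        flat = field_solution.synthesize_phi(nodes, times)
    else:                                                  # QsSolution
        if current_samples is None:
            raise ValueError("QS field synthesis needs the stimulus current samples")
        mesh = field_solution.system.mesh
        idx, w = mesh.interpolation_weights(nodes)
        base = np.einsum("pk,pk->p", field_solution.phi_unit[idx], w)
        flat = np.outer(base, current_samples)
    out = flat.reshape(len(fib_list), n_nodes, -1)
    return out[0] if single else out


def _batch_arrays(params_list):
    def col(attr):
        return np.array([getattr(p, attr) for p in params_list])[:, None]
    return {k: col(k) for k in ("c_m", "g_na_max", "g_k_max", "g_leak",
                                "e_na", "e_k", "e_leak", "g_axial")}


def simulate_fibers(ve, params_list, dt=1e-6, return_trace=False):
    """Integrate a batch of fibers driven by extracellular node potentials.

    ``ve`` has shape (n_fibers, n_nodes, n_times) in volts; ``params_list``
    gives one :class:`MembraneParams` per fiber (kinetics must agree).
    Returns ``(max_m, activated)`` where ``max_m`` has shape
    (n_fibers, n_nodes).
    """
    ve = np.asarray(ve, dtype=float)
    if ve.ndim != 3:
        raise ValueError("ve must be (n_fibers, n_nodes, n_times)")
    nf, nn, nt = ve.shape
    if len(params_list) != nf:
        raise ValueError("one MembraneParams per fiber required")
    if dt > 2e-6:
        raise ValueError("dt above 2 us is outside the validated stability range")
    kin = params_list[0].kinetics
    P = _batch_arrays(params_list)
    c_dt = P["c_m"] / dt

    m0, h0, n0 = kin.steady_state()
    v = np.zeros((nf, nn))
    m = np.full((nf, nn), m0)
    h = np.full((nf, nn), h0)
    ngate = np.full((nf, nn), n0)
    max_m = np.full((nf, nn), m0)
    trace = np.empty((nf, nn, nt)) if return_trace else None

    ga = P["g_axial"]
    # tridiagonal cable structure with sealed ends
    deg = np.full(nn, 2.0)
    deg[0] = deg[-1] = 1.0

    def laplacian(x):
        out = np.empty_like(x)
        out[:, 1:-1] = x[:, :-2] - 2.0 * x[:, 1:-1] + x[:, 2:]
        out[:, 0] = x[:, 1] - x[:, 0]
        out[:, -1] = x[:, -2] - x[:, -1]
        return out

    for step in range(nt):
        v_mv = v * 1e3
        am, bm, ah, bh, an, bn = kin.rates(v_mv)
        # exact exponential (Rush-Larsen) gating update
        for gate, a, b in ((m, am, bm), (h, ah, bh), (ngate, an, bn)):
            inf = a / (a + b)
            gate += (inf - gate) * (-np.expm1(-dt * (a + b)))
        np.maximum(max_m, m, out=max_m)

        g_na = P["g_na_max"] * m * m * h
        g_k = P["g_k_max"] * ngate * ngate
        g_ion = g_na + g_k + P["g_leak"]
        e_eff = (g_na * P["e_na"] + g_k * P["e_k"] + P["g_leak"] * P["e_leak"]) / g_ion

        rhs = c_dt * v + g_ion * e_eff + ga * laplacian(ve[:, :, step])
        diag = c_dt + g_ion + ga * deg[None, :]
        # vectorized Thomas solve across the fiber batch
        cp = np.empty((nf, nn))
        dp = np.empty((nf, nn))
        cp[:, 0] = -ga[:, 0] / diag[:, 0]
        dp[:, 0] = rhs[:, 0] / diag[:, 0]
        for i in range(1, nn):
            denom = diag[:, i] + ga[:, 0] * cp[:, i - 1]
            cp[:, i] = -ga[:, 0] / denom
            dp[:, i] = (rhs[:, i] + ga[:, 0] * dp[:, i - 1]) / denom
        v[:, -1] = dp[:, -1]
        for i in range(nn - 2, -1, -1):
            v[:, i] = dp[:, i] - cp[:, i] * v[:, i + 1]
        if not np.all(np.isfinite(v)):
            raise FloatingPointError(
                f"membrane state diverged at step {step}; reduce dt={dt:g}"
            )
        if return_trace:
            trace[:, :, step] = v
    activated = max_m.max(axis=1) > 0.7
    if return_trace:
        return max_m, activated, trace
    return max_m, activated


def simulate_fiber(ve, params: MembraneParams, dt=1e-6):
    """Single-fiber wrapper: returns (max m per node, activation flag)."""
    max_m, act = simulate_fibers(np.asarray(ve)[None], [params], dt)
    return max_m[0], bool(act[0])


def find_thresholds(
    ve_nominal,
    params_list,
    nominal_amplitude: float,
    bounds=(1e-5, 1e-2),
    dt=1e-6,
    tol=1e-3,
    amplitude_cap: float = 1.0,
):
    """Bisection thresholds for a fiber batch.

    ``ve_nominal`` is the extracellular response (n_fibers, n_nodes, n_times)
    to the stimulus at ``nominal_amplitude``; linearity of the field problem
    makes the response at amplitude A equal to ``(A/A0) * ve_nominal``.
    Brackets auto-expand by doubling/halving until they straddle the
    threshold; fibers whose upper bound reaches ``amplitude_cap`` without
    activating are flagged unconverged.  The search stops when
    ``(upper - lower)/upper < tol`` and reports the upper (activating) bound.
    """
    ve_nominal = np.asarray(ve_nominal, dtype=float)
    nf = ve_nominal.shape[0]
    lo = np.full(nf, float(bounds[0]))
    hi = np.full(nf, float(bounds[1]))
    dead = np.zeros(nf, dtype=bool)

    def activated_at(amp, sel):
        scale = (amp[sel] / nominal_amplitude)[:, None, None]
        _, act = simulate_fibers(
            ve_nominal[sel] * scale, [params_list[i] for i in np.flatnonzero(sel)], dt
        )
        return act

    # expand upper bounds until they activate (or hit the cap)
    sel = np.ones(nf, dtype=bool)
    for _ in range(40):
        if not sel.any():
            break
        act = activated_at(hi, sel)
        idx = np.flatnonzero(sel)
        need = idx[~act]
        lo[need] = np.maximum(lo[need], hi[need])
        hi[need] = hi[need] * 2.0
        dead |= np.isin(np.arange(nf), need) & (hi > amplitude_cap)
        sel = np.zeros(nf, dtype=bool)
        sel[need[hi[need] <= amplitude_cap]] = True
        if not sel.any():
            break
    # contract lower bounds until they do not activate
    sel = ~dead
    for _ in range(40):
        if not sel.any():
            break
        act = activated_at(lo, sel)
        idx = np.flatnonzero(sel)
        hot = idx[act]
        hi[hot] = np.minimum(hi[hot], lo[hot])
        lo[hot] = lo[hot] / 2.0
        sel = np.zeros(nf, dtype=bool)
        sel[hot] = True
        if not sel.any():
            break

    iters = np.zeros(nf, dtype=int)
    live = ~dead
    while True:
        open_ = live & ((hi - lo) / hi >= tol)
        if not open_.any():
            break
        mid = 0.5 * (lo + hi)
        act = activated_at(mid, open_)
        idx = np.flatnonzero(open_)
        hi[idx[act]] = mid[idx[act]]
        lo[idx[~act]] = mid[idx[~act]]
        iters[idx] += 1

    results = []
    for i in range(nf):
        if dead[i]:
            results.append(ThresholdResult(i, np.inf, False, int(iters[i])))
        else:
            results.append(ThresholdResult(i, float(hi[i]), True, int(iters[i])))
    return results


def find_threshold(
    fiber: FiberGeometry,
    field_solution,
    waveform,
    bounds=(1e-5, 1e-2),
    dt=1e-6,
    tol=1e-3,
) -> ThresholdResult:
    """Threshold of a single fiber under a solved field and stimulus."""
    times = waveform.times
    ve = extracellular_at_nodes(
        field_solution, fiber, times, current_samples=waveform.samples
    )
    params = MembraneParams.for_fiber(fiber)
    res = find_thresholds(
        ve[None], [params], waveform.amplitude, bounds=bounds, dt=dt, tol=tol
    )[0]
    return ThresholdResult(fiber.fiber_id, res.threshold_amplitude, res.converged,
                           res.iterations)
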
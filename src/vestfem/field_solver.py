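"""P1 tetrahedral FEM for the source-free complex Laplace equation.

At every stimulus frequency component the potential obeys

    -div( gamma(x, f) grad phi(x, f) ) = 0

with the complex admittivity tensor ``gamma`` (anisotropic inside nerve
bundles, rotated into the local fiber frame).  Stimulation current enters
through driven electrodes modeled as equipotential floating conductors: all
vertices of an electrode patch share one auxiliary terminal unknown and the
total current through the patch is prescribed.  The outer saline boundary is
the 0 V reference, and the lumped contact impedance Z_ET relates the metal
terminal voltage to the tissue-surface voltage, V_E = V_M + Z_ET * I (the
tissue solution itself is independent of Z_ET under current control).

Assembly is split into per-region geometric stiffness matrices computed once
per mesh (isotropic regions one matrix; nerve regions a longitudinal and a
transversal part), so the frequency loop only forms complex linear
combinations.  Systems are solved by direct sparse factorization, with a
factorization cache keyed on the admittivity values so sweeps over
frequency-independent properties refactorize only once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .electrode_circuit import InterfaceModel, z_et as interface_z_et
from .phantom import ElectrodeSpec, LabeledTetMesh
from .stimulus import StimulusSpectrum, inverse_dft

__all__ = [
    "FrequencyField",
    "SolverSystem",
    "FourierSweep",
    "QsSolution",
    "assemble",
    "apply_electrode_bc",
    "solve_frequency",
    "solve_dirichlet",
    "patch_flux",
    "solve_qs",
    "run_fourier_sweep",
]


def _is_conductive(name: str) -> bool:
    return not name.startswith("electrode")


def _gamma_for(gamma_map: dict, name: str):
    if name in gamma_map:
        return gamma_map[name]
    stem = name.rsplit("_", 1)[0]
    if stem in gamma_map:
        return gamma_map[stem]
    raise KeyError(f"region {name!r} has no admittivity mapping")


def _region_matrices(mesh: LabeledTetMesh) -> dict:
    """Per-region geometric stiffness parts, cached on the mesh object.

    Isotropic regions map to one unit-coefficient matrix; nerve regions
    (non-zero fiber axis) map to ``(K_longitudinal, K_transversal)`` built
    from the rank-one tensor ``a a^T`` and its complement.
    """
    cache = getattr(mesh, "_vestfem_region_matrices", None)
    if cache is not None:
        return cache
    n = mesh.n_vertices
    verts = mesh.vertices[mesh.tets]                       # (m,4,3)
    edges = np.stack(
        [verts[:, 1] - verts[:, 0], verts[:, 2] - verts[:, 0], verts[:, 3] - verts[:, 0]],
        axis=-1,
    )                                                      # (m,3,3) columns
    vol = np.abs(np.linalg.det(edges)) / 6.0
    inv = np.linalg.inv(edges)                             # rows: grad lambda_1..3
    grads = np.concatenate([-inv.sum(axis=1, keepdims=True), inv], axis=1)  # (m,4,3)

    rows = np.repeat(mesh.tets, 4, axis=1).reshape(-1)
    cols = np.tile(mesh.tets, (1, 4)).reshape(-1)

    def accumulate(tet_mask, k_e):
        data = k_e.reshape(-1)
        r = np.repeat(mesh.tets[tet_mask], 4, axis=1).reshape(-1)
        c = np.tile(mesh.tets[tet_mask], (1, 4)).reshape(-1)
        return sp.coo_matrix((data, (r, c)), shape=(n, n)).tocsr()

    out = {}
    for rid, name in mesh.region_names.items():
        if not _is_conductive(name):
            continue
        m = mesh.region_id == rid
        if not m.any():
            continue
        g = grads[m]
        v = vol[m]
        k_iso = np.einsum("tad,tbd,t->tab", g, g, v)
        axis = mesh.fiber_axis[m]
        if np.linalg.norm(axis, axis=1).max() > 0:
            p = np.einsum("tad,td->ta", g, axis)
            k_long = np.einsum("ta,tb,t->tab", p, p, v)
            out[name] = (accumulate(m, k_long), accumulate(m, k_iso - k_long))
        else:
            out[name] = accumulate(m, k_iso)
    mesh._vestfem_region_matrices = out
    return out


@dataclass
class SolverSystem:
    """Assembled (unconstrained) stiffness for one admittivity map."""

    mesh: LabeledTetMesh
    stiffness: sp.csr_matrix          # complex, n_vertices^2
    gamma_map: dict

    @property
    def n(self) -> int:
        return self.mesh.n_vertices


def assemble(mesh: LabeledTetMesh, gamma_map: dict) -> SolverSystem:
    """Galerkin P1 stiffness for ``-div(gamma grad phi) = 0``.

    ``gamma_map`` maps region names (or their stem, e.g. ``scar`` for
    ``scar_0``) to a complex scalar, or to ``(gamma_l, gamma_t)`` for nerve
    regions carrying a fiber axis.  Electrode interiors are excluded from the
    conductive domain.
    """
    parts = _region_matrices(mesh)
    n = mesh.n_vertices
    K = sp.csr_matrix((n, n), dtype=complex)
    for name, mat in parts.items():
        gamma = _gamma_for(gamma_map, name)
        if isinstance(mat, tuple):
            try:
                g_l, g_t = gamma
            except TypeError:
                g_l = g_t = gamma
            K = K + complex(g_l) * mat[0] + complex(g_t) * mat[1]
        else:
            if isinstance(gamma, tuple):
                raise ValueError(f"region {name!r} is isotropic; got a tensor pair")
            K = K + complex(gamma) * mat
    return SolverSystem(mesh, K.tocsr(), dict(gamma_map))


@dataclass
class FrequencyField:
    """Complex potential solution at one frequency component."""

    f: float
    phi: np.ndarray                   # (n_vertices,) complex
    v_e: dict                         # electrode name -> terminal voltage (V)
    v_m: dict                         # electrode name -> tissue-surface voltage (V)
    i_drive: dict                     # electrode name -> injected current (A)


@dataclass
class _ReducedSystem:
    system: SolverSystem
    prolong: sp.csr_matrix
    terminal_index: dict              # electrode name -> reduced dof
    currents: dict
    z_et: dict
    rhs: np.ndarray
    f: float = 0.0
    lu: object = None


def apply_electrode_bc(
    system: SolverSystem,
    electrodes: list[ElectrodeSpec],
    currents: dict,
    z_et: dict | None = None,
    f: float = 0.0,
) -> _ReducedSystem:
    """Constrain the system with equipotential driven electrodes and the
    grounded outer reference boundary.

    ``currents`` maps electrode names to complex drive currents (source and
    sink of a bipolar pair must carry opposite currents).  ``z_et`` maps
    names to lumped contact impedances used only to report V_E.
    """
    mesh = system.mesh
    z_et = dict(z_et or {})
    if "outer_boundary" not in mesh.surface_patches or not len(
        mesh.surface_patches["outer_boundary"]
    ):
        raise ValueError("mesh has no outer reference boundary; system is singular")
    driven = [e for e in electrodes if e.role in ("source", "sink")]
    roles = {e.role for e in driven}
    if len(driven) == 2 and roles == {"source", "sink"}:
        tot = sum(complex(currents[e.name]) for e in driven)
        scale = max(abs(complex(currents[e.name])) for e in driven)
        if scale > 0 and abs(tot) > 1e-9 * scale:
            raise ValueError("bipolar source/sink currents must be opposite")

    n = mesh.n_vertices
    label = np.full(n, -2, dtype=int)          # -2 free, -1 Dirichlet, >=0 terminal
    dirichlet = mesh.patch_vertices("outer_boundary")
    label[dirichlet] = -1
    terminal_index = {}
    for t, e in enumerate(driven):
        pv = mesh.patch_vertices(e.name)
        if np.any(label[pv] == -1):
            raise ValueError(f"electrode {e.name} touches the reference boundary")
        label[pv] = t

    free = np.flatnonzero(label == -2)
    n_red = len(free) + len(driven)
    row, col, val = [], [], []
    row.extend(free.tolist())
    col.extend(range(len(free)))
    val.extend([1.0] * len(free))
    for t, e in enumerate(driven):
        pv = mesh.patch_vertices(e.name)
        row.extend(pv.tolist())
        col.extend([len(free) + t] * len(pv))
        val.extend([1.0] * len(pv))
    P = sp.csr_matrix((val, (row, col)), shape=(n, n_red))

    rhs = np.zeros(n_red, dtype=complex)
    for t, e in enumerate(driven):
        terminal_index[e.name] = len(free) + t
        rhs[len(free) + t] = complex(currents[e.name])
    return _ReducedSystem(system, P, terminal_index, dict(currents), z_et, rhs, f=f)


def solve_frequency(reduced: _ReducedSystem) -> FrequencyField:
    """Direct solve of the constrained system; residual-checked."""
    P = reduced.prolong
    K_red = (P.T @ reduced.system.stiffness @ P).tocsc()
    if reduced.lu is None:
        try:
            reduced.lu = splu(K_red)
        except RuntimeError as exc:
            raise RuntimeError(f"solver breakdown at f={reduced.f:g} Hz: {exc}") from exc
    x = reduced.lu.solve(reduced.rhs)
    res = np.linalg.norm(K_red @ x - reduced.rhs)
    if res > 1e-8 * max(np.linalg.norm(reduced.rhs), 1e-300):
        raise RuntimeError(f"residual {res:g} too large at f={reduced.f:g} Hz")
    phi = P @ x
    v_m = {name: complex(x[idx]) for name, idx in reduced.terminal_index.items()}
    v_e = {
        name: v_m[name] + complex(reduced.z_et.get(name, 0.0)) * complex(reduced.currents[name])
        for name in v_m
    }
    return FrequencyField(reduced.f, phi, v_e, v_m, dict(reduced.currents))


def solve_dirichlet(system: SolverSystem, vertex_idx, values) -> np.ndarray:
    """Solve with plain inhomogeneous Dirichlet conditions (benchmark path)."""
    n = system.n
    vertex_idx = np.asarray(vertex_idx, dtype=int)
    values = np.asarray(values, dtype=complex)
    free = np.setdiff1d(np.arange(n), vertex_idx)
    K = system.stiffness.tocsc()
    phi = np.zeros(n, dtype=complex)
    phi[vertex_idx] = values
    rhs = -K[free][:, vertex_idx] @ values
    phi[free] = splu(K[free][:, free]).solve(rhs)
    return phi


def patch_flux(system: SolverSystem, phi: np.ndarray, patch: str) -> complex:
    """Current through a surface patch by consistent (Galerkin) flux.

    Summing the stiffness residual ``K phi`` over the patch vertices is the
    finite-element-consistent evaluation of the flux integral of
    ``gamma grad phi`` over the patch; for the outer boundary the sign
    convention gives the current leaving the domain as ``-patch_flux``.
    """
    r = system.stiffness @ phi
    return complex(r[system.mesh.patch_vertices(patch)].sum())


def patch_flux_geometric(system: SolverSystem, phi: np.ndarray, patch: str) -> complex:
    """Raw surface integral of ``gamma grad phi . n`` over a patch (diagnostic).

    Uses the P1 gradient of the tissue tet adjacent to each patch triangle;
    discretization error makes this less accurate than :func:`patch_flux`.
    """
    mesh = system.mesh
    tris = mesh.surface_patches[patch]
    tri_sets = [frozenset(t) for t in tris]
    lookup = {s: i for i, s in enumerate(tri_sets)}
    flux = 0.0 + 0.0j
    conductive = {
        rid for rid, name in mesh.region_names.items() if _is_conductive(name)
    }
    center = mesh.vertices[np.unique(tris)].mean(axis=0)
    for t in range(mesh.n_tets):
        if mesh.region_id[t] not in conductive:
            continue
        tet = mesh.tets[t]
        for f in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)):
            s = frozenset(tet[list(f)])
            if s not in lookup:
                continue
            a, b, c, d = mesh.vertices[tet]
            E = np.column_stack([b - a, c - a, d - a])
            inv = np.linalg.inv(E)
            grads = np.vstack([-inv.sum(axis=0), inv])
            g = grads.T @ phi[tet]
            name = mesh.region_names[mesh.region_id[t]]
            gamma = _gamma_for(system.gamma_map, name)
            if isinstance(gamma, tuple):
                ax = mesh.fiber_axis[t]
                gt = gamma[1] * g + (gamma[0] - gamma[1]) * ax * (ax @ g)
            else:
                gt = gamma * g
            p1, p2, p3 = mesh.vertices[tet[list(f)]]
            nvec = 0.5 * np.cross(p2 - p1, p3 - p1)
            if nvec @ (p1 - center) < 0:
                nvec = -nvec
            flux += gt @ nvec
    return complex(flux)


# ---------------------------------------------------------------------------
# quasi-static reference and Fourier sweep


@dataclass
class QsSolution:
    """Unit-current purely resistive solution; time series are scaled copies."""

    phi_unit: np.ndarray              # (n_vertices,) real, V per A
    v_m_unit: dict                    # electrode -> V per A
    system: SolverSystem

    def phi_series(self, weights_idx, weights, current_samples) -> np.ndarray:
        """phi(points, t) = phi_unit(points) * I(t)."""
        base = np.einsum("pk,pk->p", self.phi_unit[weights_idx].real, weights)
        return np.outer(base, current_samples)

    def electrode_series(self, name: str, current_samples) -> np.ndarray:
        return self.v_m_unit[name].real * np.asarray(current_samples)


def solve_qs(
    mesh: LabeledTetMesh,
    sigma_map: dict,
    electrodes: list[ElectrodeSpec],
) -> QsSolution:
    """One unit-current solve with real conductivities.

    The time-dependent QS potential is the unit solution scaled by the
    stimulus waveform; any probe waveform is a scalar multiple of I(t).
    """
    for k, v in sigma_map.items():
        vals = v if isinstance(v, tuple) else (v,)
        if any(abs(complex(x).imag) > 0 for x in vals):
            raise ValueError("solve_qs requires purely real conductivities")
    system = assemble(mesh, sigma_map)
    currents = {
        e.name: (1.0 if e.role == "source" else -1.0)
        for e in electrodes
        if e.role in ("source", "sink")
    }
    red = apply_electrode_bc(system, electrodes, currents)
    fld = solve_frequency(red)
    return QsSolution(fld.phi.real, {k: v for k, v in fld.v_m.items()}, system)


@dataclass
class FourierSweep:
    """Per-frequency complex fields plus synthesis helpers."""

    fields: list                       # FrequencyField per solved bin
    spectrum: StimulusSpectrum
    skipped: list = field(default_factory=list)   # bin indices not solved
    mesh: LabeledTetMesh = None

    @property
    def freqs(self) -> np.ndarray:
        return np.array([f.f for f in self.fields])

    def synthesize_phi(self, points, times) -> np.ndarray:
        """Real time series of the potential at arbitrary points (n_pts, n_t)."""
        idx, w = self.mesh.interpolation_weights(np.atleast_2d(points))
        coeff = np.stack(
            [np.einsum("pk,pk->p", f.phi[idx], w) for f in self.fields], axis=1
        )
        return inverse_dft(self.freqs, coeff, times)

    def synthesize_vertex(self, vertex_indices, times) -> np.ndarray:
        coeff = np.stack([f.phi[vertex_indices] for f in self.fields], axis=1)
        return inverse_dft(self.freqs, coeff, times)

    def electrode_series(self, name: str, times, which: str = "v_e") -> np.ndarray:
        coeff = np.array([getattr(f, which)[name] for f in self.fields])
        return inverse_dft(self.freqs, coeff, times)

    def current_series(self, name: str, times) -> np.ndarray:
        coeff = np.array([f.i_drive[name] for f in self.fields])
        return inverse_dft(self.freqs, coeff, times)


def run_fourier_sweep(
    mesh: LabeledTetMesh,
    properties: dict,
    electrodes: list[ElectrodeSpec],
    spectrum: StimulusSpectrum,
    interface: dict | None = None,
    use_permittivity: bool = True,
    magnitude_floor: float = 1e-6,
) -> FourierSweep:
    """Solve the complex Laplace problem at every significant spectrum bin.

    ``properties`` maps region names to a ``TissueProperty`` (isotropic) or a
    ``(longitudinal, transversal)`` pair (nerve).  ``interface`` optionally
    maps electrode names to :class:`InterfaceModel` for the reported V_E.
    Bins whose drive magnitude falls below ``magnitude_floor`` times the peak
    bin (and the DC bin of a charge-balanced stimulus) are skipped and
    contribute zero to any synthesis.  A factorization cache keyed on the
    admittivity values avoids refactorizing when properties are frequency
    independent.
    """
    from .dielectrics import admittivity, interp_property

    interface = dict(interface or {})
    amps = spectrum.amplitudes
    peak = np.abs(amps).max()
    fields, skipped = [], []
    # depth-1 factorization cache: consecutive bins with identical
    # admittivities (frequency-independent properties) reuse one LU, while
    # frequency-dependent sweeps never accumulate factorizations
    cache_key, cache_val = None, None

    for k, fk in enumerate(spectrum.freqs):
        if fk == 0.0 or np.abs(amps[k]) < magnitude_floor * peak:
            skipped.append(k)
            continue
        gamma_map = {}
        for name, prop in properties.items():
            if isinstance(prop, tuple):
                gl_s, gl_e = interp_property(prop[0], fk)
                gt_s, gt_e = interp_property(prop[1], fk)
                if not use_permittivity:
                    gl_e = gt_e = 0.0
                gamma_map[name] = (
                    admittivity(gl_s, gl_e, fk),
                    admittivity(gt_s, gt_e, fk),
                )
            else:
                s, e = interp_property(prop, fk)
                if not use_permittivity:
                    e = 0.0
                gamma_map[name] = admittivity(s, e, fk)

        key = tuple(
            np.round(
                np.array(
                    [complex(v) for g in gamma_map.values()
                     for v in (g if isinstance(g, tuple) else (g,))]
                ),
                14,
            )
        )
        c = amps[k]
        currents = {
            e.name: (c if e.role == "source" else -c)
            for e in electrodes
            if e.role in ("source", "sink")
        }
        z_map = {
            name: interface_z_et(model, fk) for name, model in interface.items()
        }
        if key != cache_key:
            system = assemble(mesh, gamma_map)
            red = apply_electrode_bc(system, electrodes, currents, z_map, f=fk)
            fld = solve_frequency(red)
            cache_key = key
            cache_val = (red.lu, red.prolong, red.terminal_index)
        else:
            lu, P, terminal_index = cache_val
            rhs = np.zeros(P.shape[1], dtype=complex)
            for name, idx in terminal_index.items():
                rhs[idx] = currents[name]
            x = lu.solve(rhs)
            phi = P @ x
            v_m = {name: complex(x[idx]) for name, idx in terminal_index.items()}
            v_e = {
                name: v_m[name] + z_map.get(name, 0.0) * currents[name] for name in v_m
            }
            fld = FrequencyField(fk, phi, v_e, v_m, currents)
        fields.append(fld)
    return FourierSweep(fields, spectrum, skipped, mesh)
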
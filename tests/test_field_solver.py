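"""FEM assembly, electrode boundary conditions, and frequency sweeps."""

import numpy as np
import pytest
from scipy.spatial import Delaunay

from vestfem.dielectrics import constant_property
from vestfem.electrode_circuit import InterfaceModel
from vestfem.field_solver import (
    FourierSweep,
    apply_electrode_bc,
    assemble,
    patch_flux,
    run_fourier_sweep,
    solve_dirichlet,
    solve_frequency,
    solve_qs,
)
from vestfem.phantom import (
    ElectrodeSpec,
    LabeledTetMesh,
    build_analytic_sphere,
)
from vestfem.stimulus import LONG_STIMULUS, build_biphasic, forward_dft


def _unit_cube_mesh(n=4) -> LabeledTetMesh:
    """Conforming Freudenthal-Kuhn tetrahedralization of the unit cube."""
    from itertools import permutations

    ax = np.linspace(0.0, 1.0, n)
    pts = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)

    def vid(i, j, k):
        return (i * n + j) * n + k

    basis = np.eye(3, dtype=int)
    tets = []
    for i in range(n - 1):
        for j in range(n - 1):
            for k in range(n - 1):
                base = np.array([i, j, k])
                for perm in permutations(range(3)):
                    corners = [base]
                    for p in perm:
                        corners.append(corners[-1] + basis[p])
                    tets.append([vid(*c) for c in corners])
    tets = np.asarray(tets, dtype=int)
    v = pts[tets]
    vol6 = np.einsum(
        "ij,ij->i", np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), v[:, 3] - v[:, 0]
    )
    flip = vol6 < 0
    tets[flip, 2], tets[flip, 3] = tets[flip, 3], tets[flip, 2].copy()
    return LabeledTetMesh(
        pts, tets, np.ones(len(tets), dtype=int), {1: "medium"},
        np.zeros((len(tets), 3)), {"outer_boundary": np.empty((0, 3), dtype=int)},
    )


@pytest.fixture(scope="module")
def sphere_mesh():
    return build_analytic_sphere(resolution=2.0, seed=0)


@pytest.fixture(scope="module")
def sphere_solution(sphere_mesh):
    system = assemble(sphere_mesh, {"medium": 1.0})
    spec = ElectrodeSpec("electrode_0", np.zeros(3), 150e-6, "source")
    red = apply_electrode_bc(system, [spec], {"electrode_0": 1e-3})
    return system, solve_frequency(red)


class TestAssembly:
    def test_unit_cube_linear_solution_exact(self):
        mesh = _unit_cube_mesh(4)
        system = assemble(mesh, {"medium": 1.7})
        x = mesh.vertices[:, 0]
        fixed = np.flatnonzero((x < 1e-12) | (x > 1 - 1e-12))
        phi = solve_dirichlet(system, fixed, x[fixed].astype(complex))
        assert np.max(np.abs(phi.real - x)) < 1e-10

    def test_row_sums_vanish_without_constraints(self):
        mesh = _unit_cube_mesh(4)
        system = assemble(mesh, {"medium": 2.0 + 0.3j})
        rs = np.abs(np.asarray(system.stiffness.sum(axis=1))).max()
        assert rs < 1e-12 * np.abs(system.stiffness.diagonal()).max()

    def test_isotropic_equals_uniaxial_with_equal_eigenvalues(self, coarse_phantom):
        gamma = 0.05 + 0.001j
        iso = assemble(
            coarse_phantom,
            {"fluid": 2.0, "saline": 2.0, "bone": 0.02, "nerve": gamma},
        )
        ani = assemble(
            coarse_phantom,
            {"fluid": 2.0, "saline": 2.0, "bone": 0.02, "nerve": (gamma, gamma)},
        )
        diff = (iso.stiffness - ani.stiffness).tocoo()
        worst = np.abs(diff.data).max() if diff.nnz else 0.0
        assert worst < 1e-12 * np.abs(iso.stiffness.data).max()

    def test_unmapped_region_rejected(self, coarse_phantom):
        with pytest.raises(KeyError):
            assemble(coarse_phantom, {"fluid": 2.0})


class TestElectrodeBc:
    def test_injected_current_recovered_by_flux_integral(self, sphere_solution):
        system, fld = sphere_solution
        flux = patch_flux(system, fld.phi, "electrode_0")
        assert abs(flux - 1e-3) < 0.005 * 1e-3
        out = patch_flux(system, fld.phi, "outer_boundary")
        assert abs(out + 1e-3) < 0.005 * 1e-3  # conservation over the reference

    def test_zero_interface_impedance_makes_terminal_equal_tissue(self, sphere_mesh):
        system = assemble(sphere_mesh, {"medium": 1.0})
        spec = ElectrodeSpec("electrode_0", np.zeros(3), 150e-6, "source")
        red = apply_electrode_bc(
            system, [spec], {"electrode_0": 1e-3}, z_et={"electrode_0": 0.0}
        )
        fld = solve_frequency(red)
        assert fld.v_e["electrode_0"] == fld.v_m["electrode_0"]

    def test_terminal_voltage_adds_contact_impedance_drop(self, sphere_mesh):
        system = assemble(sphere_mesh, {"medium": 1.0})
        spec = ElectrodeSpec("electrode_0", np.zeros(3), 150e-6, "source")
        z = 1e3 - 2e3j
        red = apply_electrode_bc(
            system, [spec], {"electrode_0": 1e-3}, z_et={"electrode_0": z}
        )
        fld = solve_frequency(red)
        assert fld.v_e["electrode_0"] == pytest.approx(
            fld.v_m["electrode_0"] + z * 1e-3, rel=1e-14
        )

    def test_bipolar_fluxes_balance(self, coarse_phantom_bipolar, coarse_electrodes_bipolar):
        system = assemble(
            coarse_phantom_bipolar,
            {"fluid": 2.0, "saline": 2.0, "bone": 0.02, "nerve": (0.33, 0.033)},
        )
        src = next(e for e in coarse_electrodes_bipolar if e.role == "source")
        snk = next(e for e in coarse_electrodes_bipolar if e.role == "sink")
        red = apply_electrode_bc(
            system, coarse_electrodes_bipolar, {src.name: 1e-3, snk.name: -1e-3}
        )
        fld = solve_frequency(red)
        f1 = patch_flux(system, fld.phi, src.name)
        f2 = patch_flux(system, fld.phi, snk.name)
        assert abs(f1 + f2) < 1e-3 * abs(1e-3)

    def test_unbalanced_bipolar_rejected(self, coarse_phantom_bipolar, coarse_electrodes_bipolar):
        system = assemble(
            coarse_phantom_bipolar,
            {"fluid": 2.0, "saline": 2.0, "bone": 0.02, "nerve": (0.33, 0.033)},
        )
        src = next(e for e in coarse_electrodes_bipolar if e.role == "source")
        snk = next(e for e in coarse_electrodes_bipolar if e.role == "sink")
        with pytest.raises(ValueError, match="opposite"):
            apply_electrode_bc(
                system, coarse_electrodes_bipolar, {src.name: 1e-3, snk.name: -0.5e-3}
            )

    def test_missing_reference_makes_singular_system(self, sphere_mesh):
        stripped = LabeledTetMesh(
            sphere_mesh.vertices, sphere_mesh.tets, sphere_mesh.region_id,
            sphere_mesh.region_names, sphere_mesh.fiber_axis,
            {"electrode_0": sphere_mesh.surface_patches["electrode_0"]},
            sphere_mesh.metadata,
        )
        system = assemble(stripped, {"medium": 1.0})
        spec = ElectrodeSpec("electrode_0", np.zeros(3), 150e-6, "source")
        with pytest.raises(ValueError, match="singular|reference"):
            apply_electrode_bc(system, [spec], {"electrode_0": 1e-3})


class TestSolveFrequency:
    def test_central_source_matches_closed_form_at_mid_radius(self, sphere_mesh, sphere_solution):
        _, fld = sphere_solution
        R, sigma, current = 35e-3, 1.0, 1e-3
        probes = (
            np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]])
            * R / 2
        )
        idx, w = sphere_mesh.interpolation_weights(probes)
        vals = np.einsum("pk,pk->p", fld.phi[idx].real, w)
        exact = current / (4 * np.pi * sigma) * (2 / R - 1 / R)
        assert abs(vals.mean() - exact) / exact < 0.02

    def test_real_admittivity_yields_real_solution(self, sphere_solution):
        _, fld = sphere_solution
        assert np.abs(fld.phi.imag).max() < 1e-9 * np.abs(fld.phi.real).max()

    def test_reciprocity_of_transfer_impedance(self, coarse_phantom_bipolar, coarse_electrodes_bipolar):
        system = assemble(
            coarse_phantom_bipolar,
            {"fluid": 2.0, "saline": 2.0, "bone": 0.02, "nerve": (0.33, 0.033)},
        )
        e0, e1 = coarse_electrodes_bipolar
        floating = [
            ElectrodeSpec(e0.name, e0.center, role="source"),
            ElectrodeSpec(e1.name, e1.center, role="source"),
        ]
        f1 = solve_frequency(
            apply_electrode_bc(system, floating, {e0.name: 1e-3, e1.name: 0.0})
        )
        f2 = solve_frequency(
            apply_electrode_bc(system, floating, {e0.name: 0.0, e1.name: 1e-3})
        )
        z12 = f1.v_m[e1.name] / 1e-3
        z21 = f2.v_m[e0.name] / 1e-3
        assert abs(z12 - z21) / abs(z12) < 0.005


@pytest.fixture(scope="module")
def resistive_sweep(coarse_phantom, coarse_electrodes):
    props = {
        "fluid": constant_property("csf", 1.79),
        "saline": constant_property("csf", 1.79),
        "bone": constant_property("bone", 0.02),
        "nerve": (
            constant_property("nl", 0.33),
            constant_property("nt", 0.033),
        ),
    }
    w = build_biphasic(*LONG_STIMULUS, amplitude=1e-3)
    spectrum = forward_dft(w)
    sweep = run_fourier_sweep(
        coarse_phantom, props, coarse_electrodes, spectrum, use_permittivity=False
    )
    return sweep, w


class TestQsAndSweep:
    SIGMA = {"fluid": 1.79, "saline": 1.79, "bone": 0.02, "nerve": (0.33, 0.033)}

    def test_qs_probe_waveform_is_scaled_stimulus(self, coarse_phantom, coarse_electrodes):
        qs = solve_qs(coarse_phantom, self.SIGMA, coarse_electrodes)
        w = build_biphasic(*LONG_STIMULUS, amplitude=1e-3)
        probe = np.array([[3.2e-3, 0.0, 0.0]])
        idx, wt = coarse_phantom.interpolation_weights(probe)
        series = qs.phi_series(idx, wt, w.samples)[0]
        base = series[np.argmax(np.abs(series))] / w.samples[np.argmax(np.abs(series))]
        np.testing.assert_allclose(series, base * w.samples, atol=1e-15)

    def test_qs_linearity_in_current(self, coarse_phantom, coarse_electrodes):
        qs = solve_qs(coarse_phantom, self.SIGMA, coarse_electrodes)
        w = build_biphasic(*LONG_STIMULUS, amplitude=1e-3)
        probe = np.array([[3.2e-3, 0.0, 0.0]])
        idx, wt = coarse_phantom.interpolation_weights(probe)
        s1 = qs.phi_series(idx, wt, w.samples)
        s2 = qs.phi_series(idx, wt, 2 * w.samples)
        np.testing.assert_allclose(s2, 2 * s1, rtol=1e-12)

    def test_qs_rejects_complex_conductivity(self, coarse_phantom, coarse_electrodes):
        bad = dict(self.SIGMA)
        bad["bone"] = 0.02 + 1e-4j
        with pytest.raises(ValueError):
            solve_qs(coarse_phantom, bad, coarse_electrodes)

    def test_sweep_skips_dc_and_negligible_bins(self, resistive_sweep):
        sweep, w = resistive_sweep
        assert 0 in sweep.skipped                       # charge-balanced: no DC
        assert len(sweep.fields) + len(sweep.skipped) == len(sweep.spectrum.freqs)

    def test_sweep_synthesis_is_real_and_ohmic_on_plateau(self, resistive_sweep):
        sweep, w = resistive_sweep
        t = w.times
        v_e = sweep.electrode_series("electrode_0", t)
        i_t = sweep.current_series("electrode_0", t)
        assert np.all(np.isreal(v_e))
        plateau = (t > w.onset + 30e-6) & (t < w.onset + 170e-6)
        ratio = v_e[plateau] / i_t[plateau]
        assert np.std(ratio) / np.abs(ratio.mean()) < 1e-3

    def test_frequency_independent_sweep_reuses_one_factorization(
        self, coarse_phantom, coarse_electrodes, resistive_sweep
    ):
        # all solved bins share the admittivity map, so per-bin terminal
        # voltages per unit current must coincide exactly
        sweep, _ = resistive_sweep
        z = np.array(
            [f.v_m["electrode_0"] / f.i_drive["electrode_0"] for f in sweep.fields]
        )
        assert np.abs(z - z[0]).max() < 1e-12 * abs(z[0])

    def test_zero_magnitude_bin_contributes_nothing(self, resistive_sweep):
        sweep, w = resistive_sweep
        solved = {f.f for f in sweep.fields}
        skipped_freqs = set(sweep.spectrum.freqs[sweep.skipped])
        assert solved.isdisjoint(skipped_freqs)


class TestInterfaceEffects:
    def test_tissue_voltage_invariant_under_contact_impedance(
        self, coarse_phantom, coarse_electrodes
    ):
        # current-controlled stimulation: Z_ET shifts only the terminal
        # voltage V_E, never the tissue-side solution V_M
        from vestfem.electrode_circuit import cdl_from_radius

        props = {
            "fluid": constant_property("csf", 1.79),
            "saline": constant_property("csf", 1.79),
            "bone": constant_property("bone", 0.02),
            "nerve": (constant_property("nl", 0.33), constant_property("nt", 0.033)),
        }
        w = build_biphasic(*LONG_STIMULUS, amplitude=1e-3)
        spectrum = forward_dft(w, 1e3, 20e3)  # few bins suffice for the identity
        model = InterfaceModel(cdl_from_radius(15e-6, 150e-6), r_scar=4000.0)
        bare = run_fourier_sweep(
            coarse_phantom, props, coarse_electrodes, spectrum,
            use_permittivity=False,
        )
        loaded = run_fourier_sweep(
            coarse_phantom, props, coarse_electrodes, spectrum,
            interface={"electrode_0": model}, use_permittivity=False,
        )
        for fa, fb in zip(bare.fields, loaded.fields):
            assert fb.v_m["electrode_0"] == pytest.approx(fa.v_m["electrode_0"], rel=1e-12)
            assert fb.v_e["electrode_0"] != fb.v_m["electrode_0"]

    def test_meshed_scar_thickness_raises_electrode_voltage(self):
        from vestfem.phantom import PhantomConfig, build_phantom, place_electrodes

        gam = {
            "fluid": 1.79, "saline": 1.79, "bone": 0.02,
            "nerve": (0.33, 0.033), "scar": 0.1,
        }
        peaks = []
        for th in (0.0, 300e-6, 500e-6):
            mesh = build_phantom(PhantomConfig(resolution=2.2, scar_thickness=th, seed=0))
            els = place_electrodes(mesh, "monopolar")
            system = assemble(mesh, gam)
            fld = solve_frequency(
                apply_electrode_bc(system, els, {"electrode_0": 1e-3})
            )
            peaks.append(abs(fld.v_m["electrode_0"]))
        assert peaks[0] < peaks[1] < peaks[2]
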
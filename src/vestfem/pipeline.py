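"""Scenario orchestration: phantom, fields, recruitment, selectivity, reports.

A :class:`Scenario` captures one stimulation experiment end to end — phantom
geometry, electrode mode, tissue property bounds, stimulus, solver mode (QS
or Fourier), electrode-tissue interface and power limitation, fiber counts
and seeds.  :func:`run` executes the stages and returns a results bundle (a
plain dict) holding probe waveforms, per-fiber thresholds, recruitment
curves, ROC/AUC, and a provenance log; :func:`compare` reports RMSE and
threshold/AUC deltas between two bundles sharing a probe set.

Tissue assignment: fluid cavity and saline shell carry CSF properties,
the surrounding sphere cortical-bone properties, nerve bundles the
spinal-cord curve rescaled to longitudinal/transversal conductivity at
100 Hz.  Bound tags select the uncertainty boundary per tissue: +-50 %
for nerve, a configurable log10 distance for bone and CSF (the published
boundary tables live in supplementary material, so their widths are
explicit configuration here).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dielectrics as dielec
from .dielectrics import (
    default_property,
    interp_property,
    property_bounds,
    scale_nerve_conductivity,
)
from .electrode_circuit import (
    DEFAULT_ADL,
    DEFAULT_PMAX,
    InterfaceModel,
    apply_power_limit,
    cdl_from_radius,
    scar_resistance,
)
from .field_solver import run_fourier_sweep, solve_qs
from .neural import MembraneParams, extracellular_at_nodes, find_thresholds
from .phantom import PhantomConfig, build_phantom, generate_fibers, place_electrodes, read_mesh
from .selectivity import auc, default_amplitude_grid, recruitment, rmse, roc_points, worst_case_branch
from .stimulus import LONG_STIMULUS, SHORT_STIMULUS, build_biphasic, forward_dft

__all__ = ["Scenario", "run", "compare", "tissue_properties", "save_bundle"]

#: default uncertainty widths in decades for the median-log-distance tissues
DEFAULT_LOG_DISTANCE = {"bone": 0.20, "csf": 0.05}


@dataclass
class Scenario:
    """Declarative description of one simulation experiment."""

    name: str = "scenario"
    mesh_path: str | None = None            # load instead of building
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    electrode_mode: str = "monopolar"
    solver_mode: str = "fourier"            # qs | fourier
    stimulus: str = "long"                  # long | short
    amplitude: float = 1e-3                 # A
    tissue_bounds: dict = field(default_factory=dict)   # region tissue -> tag
    use_interface: bool = False
    areal_cdl: float = DEFAULT_ADL
    scar_thickness: float = 0.0             # lumped R_scar from shell formula
    power_limit: bool = False
    p_max: float = DEFAULT_PMAX
    df: float = 1e3
    f_max: float = 500e3
    magnitude_floor: float = 1e-6
    qs_reference_freq: float = 1e3
    sigma_nerve_long: float = 0.33          # S/m at 100 Hz
    sigma_nerve_trans: float = 0.033        # S/m at 100 Hz
    bound_log_distance: dict = field(default_factory=lambda: dict(DEFAULT_LOG_DISTANCE))
    n_fibers: int = 50
    n_nodes: int = 21
    dt: float = 1e-6
    seed: int = 0
    target_branch: str = "nerve_target"

    def __post_init__(self) -> None:
        if isinstance(self.phantom, dict):
            self.phantom = PhantomConfig(**self.phantom)
        if self.solver_mode not in ("qs", "fourier"):
            raise ValueError("solver_mode must be qs or fourier")
        if self.stimulus not in ("long", "short"):
            raise ValueError("stimulus must be long or short")
        if self.scar_thickness > 0 and not self.use_interface and \
                self.phantom.scar_thickness == 0:
            raise ValueError(
                "scar thickness needs the interface model or a meshed shell"
            )
        self.phantom.electrode_mode = self.electrode_mode

    @property
    def phase_durations(self):
        return LONG_STIMULUS if self.stimulus == "long" else SHORT_STIMULUS

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def tissue_properties(scenario: Scenario) -> dict:
    """Region -> TissueProperty map honoring the scenario's bound tags."""
    csf = default_property("cerebrospinal_fluid")
    bone = default_property("cortical_bone")
    nerve = default_property("spinal_cord")
    n_long = scale_nerve_conductivity(nerve, scenario.sigma_nerve_long)
    n_trans = scale_nerve_conductivity(nerve, scenario.sigma_nerve_trans)

    def pick(prop, tissue_key, tag):
        if tag == "default":
            return prop
        if tissue_key == "nerve":
            lo, hi = property_bounds(prop, "fractional", fraction=0.5)
        else:
            d = scenario.bound_log_distance[tissue_key]
            lit = dielec.TissueProperty(
                prop.name, prop.freq_knots,
                prop.sigma_knots * 10**d, prop.eps_knots * 10**d,
            )
            lo, hi = property_bounds(prop, "median_log_distance", literature=lit)
        return {"lower": lo, "upper": hi}[tag]

    tags = dict(scenario.tissue_bounds)
    out = {
        "fluid": pick(csf, "csf", tags.get("csf", "default")),
        "saline": pick(csf, "csf", tags.get("csf", "default")),
        "bone": pick(bone, "bone", tags.get("bone", "default")),
        "nerve": (
            pick(n_long, "nerve", tags.get("nerve", "default")),
            pick(n_trans, "nerve", tags.get("nerve", "default")),
        ),
    }
    out["scar"] = dielec.constant_property("scar", 0.1)
    return out


def _sigma_map(props: dict, f_ref: float) -> dict:
    out = {}
    for name, prop in props.items():
        if isinstance(prop, tuple):
            out[name] = tuple(interp_property(p, f_ref)[0] for p in prop)
        else:
            out[name] = interp_property(prop, f_ref)[0]
    return out


def _probe_points(mesh) -> dict:
    """Named probe locations: just inside each nerve bundle at its root."""
    probes = {}
    for name, info in mesh.metadata.get("bundles", {}).items():
        a = np.asarray(info["start"])
        u = np.asarray(info["direction"])
        probes[name] = a + 0.5e-3 * u
    return probes


def run(scenario: Scenario) -> dict:
    """Execute a scenario; returns the results bundle."""
    log = []

    def note(msg):
        log.append(msg)

    if scenario.mesh_path:
        mesh = read_mesh(scenario.mesh_path)
        note(f"mesh loaded from {scenario.mesh_path}")
    else:
        mesh = build_phantom(scenario.phantom)
        note(f"phantom built: {mesh.n_vertices} vertices, {mesh.n_tets} tets")
    electrodes = place_electrodes(
        mesh, scenario.electrode_mode,
        areal_cdl=scenario.areal_cdl, scar_thickness=scenario.scar_thickness,
    )

    pd_dur, gap = scenario.phase_durations
    waveform = build_biphasic(pd_dur, gap, scenario.amplitude, dt=scenario.dt)
    spectrum = forward_dft(waveform, scenario.df, scenario.f_max)
    times = waveform.times

    props = tissue_properties(scenario)
    interface = {}
    r_scar = 0.0
    if scenario.use_interface:
        for e in electrodes:
            c_dl = cdl_from_radius(scenario.areal_cdl, e.radius)
            r_scar = scar_resistance(e.radius, scenario.scar_thickness)
            interface[e.name] = InterfaceModel(c_dl, r_scar, scenario.p_max)
        note(f"interface: C_dl={c_dl:.3e} F, R_scar={r_scar:.1f} ohm")

    probes = _probe_points(mesh)
    source = next(e for e in electrodes if e.role == "source")

    if scenario.solver_mode == "qs":
        sigma_map = _sigma_map(props, scenario.qs_reference_freq)
        field_solution = solve_qs(mesh, sigma_map, electrodes)
        note(f"QS solve at sigma({scenario.qs_reference_freq:g} Hz)")
        probe_series = {}
        for name, p in probes.items():
            idx, w = mesh.interpolation_weights(np.atleast_2d(p))
            probe_series[name] = field_solution.phi_series(idx, w, waveform.samples)[0]
        v_m = field_solution.electrode_series(source.name, waveform.samples)
        v_e = v_m + r_scar * waveform.samples if scenario.use_interface else v_m.copy()
        i_t = waveform.samples.copy()
    else:
        sweep = run_fourier_sweep(
            mesh, props, electrodes, spectrum,
            interface=interface, magnitude_floor=scenario.magnitude_floor,
        )
        field_solution = sweep
        note(
            f"Fourier sweep: {len(sweep.fields)} bins solved, "
            f"{len(sweep.skipped)} skipped"
        )
        pts = np.array(list(probes.values()))
        series = sweep.synthesize_phi(pts, times)
        probe_series = {name: series[i] for i, name in enumerate(probes)}
        v_e = sweep.electrode_series(source.name, times, which="v_e")
        v_m = sweep.electrode_series(source.name, times, which="v_m")
        i_t = sweep.current_series(source.name, times)

    power_scale = 1.0
    if scenario.power_limit:
        power_scale, v_e_lim, i_lim = apply_power_limit(v_e, i_t, scenario.p_max)
        note(f"power limit: peak P={np.max(v_e * i_t):.3e} W, scale={power_scale:.4f}")
    amplitude_cap = scenario.amplitude * power_scale if scenario.power_limit else np.inf

    branches = list(mesh.metadata.get("bundles", {})) if scenario.n_fibers > 0 else []
    thresholds = {}
    all_fibers = {}
    if branches:
        # one bisection batch across every branch: the cable integrator is
        # vectorized over fibers, so merging branches shares the stepping cost
        for branch in branches:
            all_fibers[branch] = generate_fibers(
                mesh, branch, n=scenario.n_fibers, seed=scenario.seed,
                n_nodes=scenario.n_nodes,
            )
        fibers_flat = [f for b in branches for f in all_fibers[b]]
        ve = extracellular_at_nodes(
            field_solution, fibers_flat, times, current_samples=waveform.samples
        )
        params = [MembraneParams.for_fiber(f) for f in fibers_flat]
        res_flat = find_thresholds(ve, params, scenario.amplitude, dt=scenario.dt)
        k = 0
        for branch in branches:
            n = len(all_fibers[branch])
            thresholds[branch] = [
                type(r)(all_fibers[branch][i].fiber_id, r.threshold_amplitude,
                        r.converged, r.iterations)
                for i, r in enumerate(res_flat[k : k + n])
            ]
            k += n
            n_conv = sum(r.converged for r in thresholds[branch])
            note(f"{branch}: {n_conv}/{n} thresholds converged")

    flat = [t for res in thresholds.values() for t in res]
    grid = default_amplitude_grid(flat) if any(t.converged for t in flat) else np.array([])
    curves = {}
    for branch in branches if len(grid) else []:
        eff = [
            t if (not t.converged or t.threshold_amplitude <= amplitude_cap)
            else type(t)(t.fiber_id, np.inf, False, t.iterations)
            for t in thresholds[branch]
        ]
        try:
            curves[branch] = recruitment(eff, grid, branch)
        except ValueError:
            note(f"{branch}: no converged thresholds under the power cap")
    target = scenario.target_branch
    roc = auc_val = worst = None
    nontargets = [c for b, c in curves.items() if b != target]
    if target in curves and nontargets:
        roc = roc_points(curves[target], nontargets)
        auc_val = auc(roc)
        worst = worst_case_branch(nontargets)
        note(f"AUC={auc_val:.4f}, worst-case branch={worst}")

    threshold_table = pd.DataFrame(
        [
            {
                "branch": b,
                "fiber_id": t.fiber_id,
                "type": all_fibers[b][t.fiber_id].afferent_type,
                "threshold_A": t.threshold_amplitude,
                "converged": t.converged,
                "iterations": t.iterations,
            }
            for b in branches
            for t in thresholds[b]
        ]
    )

    return {
        "scenario": asdict(scenario),
        "config_hash": scenario.config_hash(),
        "mesh_stats": {"n_vertices": mesh.n_vertices, "n_tets": mesh.n_tets},
        "times": times,
        "stimulus": waveform,
        "probe_series": probe_series,
        "electrode_series": {"v_e": v_e, "v_m": v_m, "current": i_t},
        "power_scale": power_scale,
        "amplitude_cap": amplitude_cap,
        "skipped_bins": getattr(field_solution, "skipped", []),
        "thresholds": thresholds,
        "threshold_table": threshold_table,
        "amplitude_grid": grid,
        "recruitment": curves,
        "roc_points": roc,
        "auc": auc_val,
        "worst_case_branch": worst,
        "log": log,
    }


def compare(bundle_a: dict, bundle_b: dict) -> dict:
    """Probe-by-probe RMSE and threshold/AUC deltas between two runs."""
    probes_a = set(bundle_a["probe_series"])
    probes_b = set(bundle_b["probe_series"])
    if probes_a != probes_b:
        raise ValueError("bundles do not share a probe set")
    times = bundle_a["times"]
    if len(times) != len(bundle_b["times"]) or not np.allclose(times, bundle_b["times"]):
        raise ValueError("bundles do not share a time grid")
    w = bundle_a["stimulus"]
    rows = []
    for name in sorted(probes_a):
        rows.append(
            {
                "probe": name,
                "rmse_V": rmse(
                    bundle_a["probe_series"][name],
                    bundle_b["probe_series"][name],
                    times, w.onset, w.stim_end,
                ),
            }
        )
    rows.append(
        {
            "probe": "electrode_v_e",
            "rmse_V": rmse(
                bundle_a["electrode_series"]["v_e"],
                bundle_b["electrode_series"]["v_e"],
                times, w.onset, w.stim_end,
            ),
        }
    )
    deltas = {}
    for branch in bundle_a["thresholds"]:
        if branch not in bundle_b["thresholds"]:
            continue
        ta = {t.fiber_id: t for t in bundle_a["thresholds"][branch] if t.converged}
        tb = {t.fiber_id: t for t in bundle_b["thresholds"][branch] if t.converged}
        shared = sorted(set(ta) & set(tb))
        if shared:
            deltas[branch] = float(
                np.mean(
                    [tb[i].threshold_amplitude - ta[i].threshold_amplitude for i in shared]
                )
            )
    auc_a, auc_b = bundle_a.get("auc"), bundle_b.get("auc")
    return {
        "rmse_table": pd.DataFrame(rows),
        "threshold_delta_A": deltas,
        "auc_a": auc_a,
        "auc_b": auc_b,
        "auc_delta": None if auc_a is None or auc_b is None else auc_b - auc_a,
        "worst_case": {
            "a": bundle_a.get("worst_case_branch"),
            "b": bundle_b.get("worst_case_branch"),
        },
    }


def save_bundle(bundle: dict, outdir) -> None:
    """Write a bundle as tabular text + JSON summary + run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle["threshold_table"].to_csv(outdir / "thresholds.tsv", sep="\t", index=False)
    times = bundle["times"]
    probe_df = pd.DataFrame({"time_s": times})
    for name, series in bundle["probe_series"].items():
        probe_df[name + "_V"] = series
    for name, series in bundle["electrode_series"].items():
        probe_df["electrode_" + name] = series
    probe_df.to_csv(outdir / "probe_waveforms.tsv", sep="\t", index=False)
    if bundle["recruitment"]:
        rec = pd.DataFrame({"amplitude_A": bundle["amplitude_grid"]})
        for branch, curve in bundle["recruitment"].items():
            rec[branch] = curve.fraction_active
        rec.to_csv(outdir / "recruitment.tsv", sep="\t", index=False)
    summary = {
        "config_hash": bundle["config_hash"],
        "mesh_stats": bundle["mesh_stats"],
        "auc": bundle["auc"],
        "worst_case_branch": bundle["worst_case_branch"],
        "power_scale": bundle["power_scale"],
        "amplitude_cap": None if np.isinf(bundle["amplitude_cap"]) else bundle["amplitude_cap"],
        "n_skipped_bins": len(bundle["skipped_bins"]),
        "scenario": bundle["scenario"],
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    (outdir / "run.log").write_text("\n".join(bundle["log"]) + "\n")
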
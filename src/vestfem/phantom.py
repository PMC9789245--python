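"""Parametric labeled tetrahedral phantom of an implanted vestibular cavity.

The anatomical labyrinth is replaced by the minimum structure on which
recruitment selectivity is meaningful: a conductive fluid cavity holding
spherical stimulation electrodes, one target and two (or more) non-target
anisotropic nerve bundles running radially outward, all embedded in a 25 mm
bone sphere surrounded by a 10 mm saline shell.  The outer saline surface is
the reference boundary (0 V).

Meshing strategy: a graded point cloud (fine near the electrodes, coarsening
with distance) is tetrahedralized with Delaunay; tetrahedra are labeled by
their centroid, electrode surfaces become conforming internal triangle
patches, and nerve tetrahedra carry the local fiber-axis unit vector for the
anisotropic admittivity tensor.

Meshes round-trip losslessly through Gmsh MSH 2.2 ASCII (regions and patches
as physical groups, fiber axes as element data, phantom metadata in a
vendor section that standard readers skip) and export to legacy VTK for
viewers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import Delaunay, cKDTree

__all__ = [
    "PhantomConfig",
    "ElectrodeSpec",
    "FiberGeometry",
    "LabeledTetMesh",
    "build_phantom",
    "build_analytic_sphere",
    "place_electrodes",
    "electrode_positions",
    "generate_fibers",
    "read_mesh",
    "write_mesh",
    "write_vtk",
]

#: Default afferent-type mix and fiber outer diameters (implementation
#: defaults; the source neural-model literature tabulates type statistics).
DEFAULT_TYPE_MIX = {"calyx": 0.15, "dimorphic": 0.70, "bouton": 0.15}
DEFAULT_DIAMETERS = {"calyx": 4.0e-6, "dimorphic": 3.0e-6, "bouton": 2.0e-6}


@dataclass(frozen=True)
class ElectrodeSpec:
    """A spherical stimulation electrode embedded in the fluid cavity."""

    name: str
    center: np.ndarray            # m
    radius: float = 150e-6        # m
    role: str = "source"          # source | sink | reference
    areal_cdl: float = 15e-6      # F/cm^2
    scar_thickness: float = 0.0   # m

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.radius <= 0:
            raise ValueError("electrode radius must be positive")
        if self.role not in ("source", "sink", "reference"):
            raise ValueError("role must be source/sink/reference")
        if self.scar_thickness < 0:
            raise ValueError("scar thickness must be non-negative")


@dataclass(frozen=True)
class FiberGeometry:
    """Node-of-Ranvier chain of one myelinated afferent."""

    fiber_id: int
    branch: str
    node_positions: np.ndarray    # (n_nodes, 3) m
    internode_length: float       # m
    diameter: float               # m, outer fiber diameter
    afferent_type: str

    def __post_init__(self) -> None:
        p = np.asarray(self.node_positions, dtype=float)
        object.__setattr__(self, "node_positions", p)
        if self.afferent_type not in DEFAULT_DIAMETERS:
            raise ValueError(f"unknown afferent type {self.afferent_type!r}")
        gaps = np.linalg.norm(np.diff(p, axis=0), axis=1)
        if np.any(np.abs(gaps - self.internode_length) > 0.01 * self.internode_length):
            raise ValueError("node spacing deviates from internode length by > 1 %")


@dataclass
class PhantomConfig:
    """Geometry and resolution of the synthetic phantom.

    ``resolution`` is a global coarsening multiplier on local edge length
    (1.0 is the default desk-scale mesh of roughly 1e5 tetrahedra).
    """

    cavity_radius: float = 3.5e-3
    bone_radius: float = 25e-3
    saline_thickness: float = 10e-3
    nerve_radius: float = 0.6e-3
    nerve_start: float = 2.9e-3
    nerve_length: float = 9.0e-3
    # bundle axis directions: first entry is the target branch
    bundle_angles_deg: tuple = (0.0, 50.0, 100.0)
    electrode_mode: str = "monopolar"
    electrode_radius: float = 150e-6
    epithelium_setback: float = 0.4e-3   # epithelium center sits this far
                                         # proximal of the nerve face, in fluid
    scar_thickness: float = 0.0          # meshed scar shell; 0 = none (lumped)
    resolution: float = 1.0
    seed: int = 0

    @property
    def outer_radius(self) -> float:
        return self.bone_radius + self.saline_thickness

    def bundle_direction(self, k: int) -> np.ndarray:
        a = np.deg2rad(self.bundle_angles_deg[k])
        return np.array([np.cos(a), np.sin(a), 0.0])

    def bundle_names(self) -> list[str]:
        return ["nerve_target"] + [
            f"nerve_nontarget{k}" for k in range(1, len(self.bundle_angles_deg))
        ]

    @property
    def epithelium_center(self) -> np.ndarray:
        u = self.bundle_direction(0)
        return (self.nerve_start - self.epithelium_setback) * u

    @property
    def transversal_axis(self) -> np.ndarray:
        # any unit vector orthogonal to the target bundle axis
        u = self.bundle_direction(0)
        t = np.cross([0.0, 0.0, 1.0], u)
        return t / np.linalg.norm(t)


@dataclass
class LabeledTetMesh:
    """Labeled tetrahedral mesh with surface patches and fiber axes."""

    vertices: np.ndarray                  # (n, 3) m
    tets: np.ndarray                      # (m, 4) int, positively oriented
    region_id: np.ndarray                 # (m,) int
    region_names: dict                    # id -> name
    fiber_axis: np.ndarray                # (m, 3), zero outside nerve regions
    surface_patches: dict                 # name -> (k, 3) int vertex triples
    metadata: dict = field(default_factory=dict)
    _centroid_tree: cKDTree | None = field(default=None, repr=False, compare=False)

    # -- basic queries ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def region_tets(self, name: str) -> np.ndarray:
        ids = [i for i, n in self.region_names.items() if n == name]
        if not ids:
            raise KeyError(f"no region named {name!r}")
        return np.flatnonzero(np.isin(self.region_id, ids))

    def tet_volumes(self) -> np.ndarray:
        v = self.vertices[self.tets]
        return np.abs(np.einsum(
            "ij,ij->i",
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]),
            v[:, 3] - v[:, 0],
        )) / 6.0

    def region_volume(self, name: str) -> float:
        return float(self.tet_volumes()[self.region_tets(name)].sum())

    def patch_vertices(self, name: str) -> np.ndarray:
        return np.unique(self.surface_patches[name])

    def patch_area(self, name: str) -> float:
        tri = self.vertices[self.surface_patches[name]]
        return float(
            0.5 * np.linalg.norm(
                np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
            ).sum()
        )

    # -- point location --------------------------------------------------

    def locate(self, points: np.ndarray, k: int = 48):
        """Find containing tetrahedra and barycentric coordinates.

        Candidate tets come from a centroid KD-tree; each candidate is tested
        by its barycentric coordinates.  Returns ``(tet_index, bary)`` with
        tet_index -1 for points outside the mesh.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self._centroid_tree is None:
            centroids = self.vertices[self.tets].mean(axis=1)
            self._centroid_tree = cKDTree(centroids)
        _, cand = self._centroid_tree.query(points, k=min(k, self.n_tets))
        cand = np.atleast_2d(cand)
        tet_idx = np.full(len(points), -1, dtype=int)
        bary = np.zeros((len(points), 4))
        verts = self.vertices
        for i, p in enumerate(points):
            for t in cand[i]:
                a, b, c, d = verts[self.tets[t]]
                mat = np.column_stack([b - a, c - a, d - a])
                try:
                    lam = np.linalg.solve(mat, p - a)
                except np.linalg.LinAlgError:
                    continue
                lam0 = 1.0 - lam.sum()
                if lam0 >= -1e-9 and np.all(lam >= -1e-9):
                    tet_idx[i] = t
                    bary[i] = np.concatenate([[lam0], lam])
                    break
        return tet_idx, bary

    def interpolation_weights(self, points: np.ndarray):
        """Sparse barycentric interpolation matrix rows for ``points``.

        Returns ``(vertex_indices (n,4), weights (n,4))``; raises if any
        point falls outside the mesh.
        """
        tet_idx, bary = self.locate(points)
        if np.any(tet_idx < 0):
            bad = np.flatnonzero(tet_idx < 0)
            raise ValueError(f"points outside mesh at indices {bad[:5].tolist()}")
        return self.tets[tet_idx], bary

    # -- quality ---------------------------------------------------------

    def min_dihedral_angle(self) -> float:
        """Minimum dihedral angle over all tets, degrees."""
        v = self.vertices[self.tets]
        # outward unit normal of the face opposite each vertex
        faces = [(1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2)]
        normals = []
        for opp, (a, b, c) in enumerate(faces):
            n = np.cross(v[:, b] - v[:, a], v[:, c] - v[:, a])
            n /= np.linalg.norm(n, axis=1, keepdims=True)
            # flip so the normal points away from the opposite vertex
            sign = np.sign(np.einsum("ij,ij->i", n, v[:, a] - v[:, opp]))
            normals.append(n * sign[:, None])
        min_cos = np.full(len(v), 1.0)
        for i in range(4):
            for j in range(i + 1, 4):
                cosang = np.einsum("ij,ij->i", normals[i], normals[j])
                min_cos = np.minimum(min_cos, cosang)
        # interior dihedral theta obeys cos(theta) = -n1.n2 for outward
        # normals, i.e. theta = pi - arccos(n1.n2); slivers drive n1.n2 -> -1
        ang = np.degrees(np.pi - np.arccos(np.clip(min_cos, -1.0, 1.0)))
        return float(ang.min())


# ---------------------------------------------------------------------------
# point cloud generation


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _sphere_points(center, radius, spacing, rng) -> np.ndarray:
    n = max(12, int(np.ceil(4 * np.pi * radius**2 / spacing**2)))
    pts = _fibonacci_sphere(n) @ _random_rotation(rng).T
    return center + radius * pts


def _shell_cloud(center, r_in, r_out, h_of_r, rng, radial_jitter=0.3) -> np.ndarray:
    """Concentric jittered point shells between two radii with local spacing."""
    out = []
    r = r_in
    while r < r_out:
        h = h_of_r(r)
        pts = _sphere_points(np.zeros(3), r, h, rng)
        pts *= (1 + radial_jitter * (rng.random(len(pts))[:, None] - 0.5) * h / r)
        out.append(center + pts)
        r += h
    return np.vstack(out) if out else np.empty((0, 3))


def _box_grid(spacing, half_extent, rng, jitter=0.35) -> np.ndarray:
    ax = np.arange(-half_extent, half_extent + spacing, spacing)
    g = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    return g + jitter * spacing * (rng.random(g.shape) - 0.5) * 2


def _cylinder_cloud(start, direction, length, radius, spacing, rng) -> np.ndarray:
    """Jittered cylindrical lattice including surface rings."""
    u = direction / np.linalg.norm(direction)
    a = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(u, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    pts = []
    n_ax = int(np.ceil(length / spacing)) + 1
    radii = np.arange(0, radius + 0.5 * spacing, spacing)
    radii[-1] = radius
    for s in np.linspace(0, length, n_ax):
        for r in radii:
            n_ring = max(1, int(np.ceil(2 * np.pi * r / spacing)))
            th = np.linspace(0, 2 * np.pi, n_ring, endpoint=False)
            th += rng.random() * 2 * np.pi
            ring = start + s * u + r * (np.outer(np.cos(th), e1) + np.outer(np.sin(th), e2))
            if r > 0:
                ring += 0.25 * spacing * (rng.random(ring.shape) - 0.5)
            pts.append(ring)
    return np.vstack(pts)


def _dist_to_segment(points, a, u, length) -> np.ndarray:
    """Distance from points to the axis segment a + s*u, s in [0, length]."""
    rel = points - a
    s = np.clip(rel @ u, 0.0, length)
    return np.linalg.norm(rel - np.outer(s, u), axis=1)


def _dist_to_cylinder(points, a, u, length, radius) -> np.ndarray:
    """Distance from points to a capped cylinder (0 inside)."""
    rel = np.atleast_2d(points) - a
    s = rel @ u
    radial = np.linalg.norm(rel - np.outer(s, u), axis=1)
    dr = np.maximum(radial - radius, 0.0)
    ds = np.maximum(np.maximum(-s, s - length), 0.0)
    return np.hypot(dr, ds)


# ---------------------------------------------------------------------------
# phantom assembly


def electrode_positions(mode: str, epithelium_center, axis) -> list[tuple[str, np.ndarray]]:
    """Electrode roles and centers along the transversal axis.

    Monopolar: one source 750 um from the epithelium center.  Bipolar: a
    source at 250 um and a sink at 1250 um (inverted current).
    """
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("transversal axis must have non-zero length")
    t = axis / norm
    e = np.asarray(epithelium_center, dtype=float)
    if mode == "monopolar":
        return [("source", e + 750e-6 * t)]
    if mode == "bipolar":
        return [("source", e + 250e-6 * t), ("sink", e + 1250e-6 * t)]
    raise ValueError(f"unknown electrode mode {mode!r}")


def _orient_tets(vertices, tets):
    v = vertices[tets]
    vol6 = np.einsum(
        "ij,ij->i",
        np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]),
        v[:, 3] - v[:, 0],
    )
    flip = vol6 < 0
    tets = tets.copy()
    tets[flip, 2], tets[flip, 3] = tets[flip, 3], tets[flip, 2].copy()
    return tets, np.abs(vol6) / 6.0


def _boundary_faces(tets, mask):
    """Faces separating tets in ``mask`` from tets outside it (or the hull)."""
    faces = {}
    sel = np.flatnonzero(mask)
    face_ids = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
    all_faces = {}
    for t in range(len(tets)):
        for f in face_ids:
            key = tuple(sorted(tets[t][list(f)]))
            all_faces.setdefault(key, []).append(t)
    out = []
    inside = set(sel.tolist())
    for t in sel:
        for f in face_ids:
            tri = tets[t][list(f)]
            key = tuple(sorted(tri))
            owners = all_faces[key]
            if len(owners) == 1 or any(o not in inside for o in owners if o != t):
                out.append(tri)
    return np.array(out, dtype=int) if out else np.empty((0, 3), dtype=int)


def build_phantom(cfg: PhantomConfig) -> LabeledTetMesh:
    """Generate the labeled phantom mesh for a stimulation scenario.

    Regions: ``fluid`` (cavity, CSF-like), one target and >= 2 non-target
    nerve bundles, ``bone``, ``saline``, optional ``scar`` shells, and one
    ``electrode_<k>`` region per contact whose boundary triangles form the
    conforming electrode patch.  The convex hull of the saline sphere is the
    ``outer_boundary`` patch (reference electrode).
    """
    rng = np.random.default_rng(cfg.seed)
    res = cfg.resolution
    if res <= 0:
        raise ValueError("resolution must be positive")
    r_cav, r_bone, r_out = cfg.cavity_radius, cfg.bone_radius, cfg.outer_radius
    if not (0 < r_cav < r_bone < r_out):
        raise ValueError("require cavity < bone < outer radius")

    electrodes = electrode_positions(
        cfg.electrode_mode, cfg.epithelium_center, cfg.transversal_axis
    )
    e_centers = np.array([c for _, c in electrodes])
    r_e = cfg.electrode_radius

    bundles = []
    for k, name in enumerate(cfg.bundle_names()):
        u = cfg.bundle_direction(k)
        bundles.append((name, cfg.nerve_start * u, u))
    # geometric sanity: bundles pairwise disjoint, electrodes in the fluid
    for i in range(len(bundles)):
        for j in range(i + 1, len(bundles)):
            ai, ui = bundles[i][1], bundles[i][2]
            aj, uj = bundles[j][1], bundles[j][2]
            probe = ai + np.outer(np.linspace(0, cfg.nerve_length, 60), ui)
            if np.any(
                _dist_to_cylinder(probe, aj, uj, cfg.nerve_length, cfg.nerve_radius)
                < cfg.nerve_radius
            ):
                raise ValueError("nerve bundles overlap")
    for _, c in electrodes:
        if np.linalg.norm(c) + r_e + cfg.scar_thickness > r_cav:
            raise ValueError("electrode leaves the fluid cavity")
        # the metal contact must not touch nerve; a scar shell may carve into
        # it (encapsulation displaces tissue)
        for name, a, u in bundles:
            if _dist_to_cylinder(c[None], a, u, cfg.nerve_length, cfg.nerve_radius)[0] < r_e:
                raise ValueError(f"electrode intersects {name}")

    # the contact is tiny relative to the domain: its surface sampling only
    # coarsens mildly with the global resolution multiplier
    h_e0 = 55e-6 * min(res, 1.2)
    h_tube = 0.28e-3 * res
    h_cav = 0.32e-3 * res
    h_max = 3.2e-3 * res

    def h_bulk(r):
        return min(h_max, h_cav + 0.45 * max(0.0, r - r_cav))

    def d_elec(pts):
        return np.min(
            np.linalg.norm(pts[:, None, :] - e_centers[None], axis=2), axis=1
        ) - r_e

    def d_tube(pts):
        d = np.full(len(pts), np.inf)
        for _, a, u in bundles:
            d = np.minimum(
                d, _dist_to_segment(pts, a, u, cfg.nerve_length) - cfg.nerve_radius
            )
        return d

    surf = []
    for _, c in electrodes:
        surf.append(_sphere_points(c, r_e, h_e0, rng))
        if cfg.scar_thickness > 0:
            surf.append(_sphere_points(c, r_e + cfg.scar_thickness, 2.2 * h_e0 + 0.3 * cfg.scar_thickness, rng))
    surf.append(_sphere_points(np.zeros(3), r_cav, h_cav, rng))
    surf.append(_sphere_points(np.zeros(3), r_bone, min(h_max, h_bulk(r_bone)) * 0.9, rng))
    surf.append(_sphere_points(np.zeros(3), r_out, h_max * 0.9, rng))
    surf = np.vstack(surf)

    vol = []
    # fine neighborhood of each electrode
    for _, c in electrodes:
        local = _shell_cloud(
            c, r_e + 0.8 * h_e0, 0.45e-3, lambda d: h_e0 + 0.5 * (d - r_e), rng
        )
        vol.append(local)
    # nerve tubes (surface rings included)
    for _, a, u in bundles:
        vol.append(_cylinder_cloud(a, u, cfg.nerve_length, cfg.nerve_radius, h_tube, rng))
    # cavity interior
    cav = _box_grid(h_cav, r_cav, rng)
    r = np.linalg.norm(cav, axis=1)
    keep = (r < r_cav - 0.45 * h_cav) & (d_elec(cav) > 0.5e-3) & (d_tube(cav) > 0.5 * h_tube)
    vol.append(cav[keep])
    # bone and saline shells
    bulk = _shell_cloud(np.zeros(3), r_cav + 0.6 * h_cav, r_out - 0.55 * h_max, h_bulk, rng)
    rb = np.linalg.norm(bulk, axis=1)
    keep = (
        (d_tube(bulk) > 0.6 * h_tube)
        & (np.abs(rb - r_bone) > 0.45 * h_bulk(r_bone))
        & (np.abs(rb - r_cav) > 0.45 * h_cav)
        & (rb < r_out - 0.5 * h_max)
    )
    vol.append(bulk[keep])
    vol = np.vstack(vol)

    # drop volume points crowding the explicit surfaces or inside electrodes
    tree = cKDTree(surf)
    dist, _ = tree.query(vol, k=1)
    local_h = np.minimum(
        h_max,
        np.minimum(
            h_e0 + 0.5 * np.maximum(d_elec(vol), 0.0),
            np.minimum(h_tube + 0.7 * np.maximum(d_tube(vol), 0.0),
                       np.array([h_bulk(x) for x in np.linalg.norm(vol, axis=1)])),
        ),
    )
    keep = (dist > 0.45 * local_h) & (d_elec(vol) > 0.4 * h_e0)
    if cfg.scar_thickness > 0:
        dsc = d_elec(vol)
        keep &= ~((dsc > -r_e) & (np.abs(dsc - cfg.scar_thickness) < 0.5 * h_e0))
    points = np.vstack([surf, vol[keep]])

    mesh = _tetrahedralize_and_label(points, cfg, electrodes, bundles)
    return mesh


def _tetrahedralize_and_label(points, cfg, electrodes, bundles) -> LabeledTetMesh:
    tri = Delaunay(points)
    tets, volumes = _orient_tets(points, tri.simplices)
    good = volumes > 1e-22
    tets, volumes = tets[good], volumes[good]

    centroids = points[tets].mean(axis=1)
    vmax = np.linalg.norm(points[tets], axis=2).max(axis=1)
    r_cent = np.linalg.norm(centroids, axis=1)

    region_names = {}
    region_id = np.zeros(len(tets), dtype=int)
    fiber_axis = np.zeros((len(tets), 3))
    next_id = 1

    def add_region(name):
        nonlocal next_id
        region_names[next_id] = name
        next_id += 1
        return next_id - 1

    unassigned = np.ones(len(tets), dtype=bool)
    # electrodes first (tets fully inside the contact sphere)
    for k, (_, c) in enumerate(electrodes):
        rid = add_region(f"electrode_{k}")
        d_cent = np.linalg.norm(centroids - c, axis=1)
        d_max = np.linalg.norm(points[tets] - c, axis=2).max(axis=1)
        m = unassigned & (d_cent < cfg.electrode_radius) & (d_max < cfg.electrode_radius * (1 + 1e-6))
        region_id[m] = rid
        unassigned &= ~m
        if cfg.scar_thickness > 0:
            sid = add_region(f"scar_{k}")
            m = unassigned & (d_cent < cfg.electrode_radius + cfg.scar_thickness)
            region_id[m] = sid
            unassigned &= ~m
    # nerve bundles
    for name, a, u in bundles:
        rid = add_region(name)
        rel = centroids - a
        s = rel @ u
        radial = np.linalg.norm(rel - np.outer(s, u), axis=1)
        m = unassigned & (s >= 0) & (s <= cfg.nerve_length) & (radial <= cfg.nerve_radius)
        region_id[m] = rid
        fiber_axis[m] = u
        unassigned &= ~m
    # fluid / bone / saline by centroid radius
    rid = add_region("fluid")
    m = unassigned & (r_cent < cfg.cavity_radius)
    region_id[m] = rid
    unassigned &= ~m
    rid = add_region("bone")
    m = unassigned & (r_cent < cfg.bone_radius)
    region_id[m] = rid
    unassigned &= ~m
    rid = add_region("saline")
    region_id[unassigned] = rid

    # surface patches
    patches = {}
    names = dict(region_names)
    inv = {v: k for k, v in names.items()}
    for k in range(len(electrodes)):
        mask = region_id == inv[f"electrode_{k}"]
        patches[f"electrode_{k}"] = _boundary_faces(tets, mask)
    hull_faces = []
    # hull faces: faces belonging to exactly one tet
    face_count = {}
    face_ids = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
    for t in range(len(tets)):
        for f in face_ids:
            key = tuple(sorted(tets[t][list(f)]))
            face_count[key] = face_count.get(key, 0) + 1
    for key, cnt in face_count.items():
        if cnt == 1:
            hull_faces.append(key)
    patches["outer_boundary"] = np.array(hull_faces, dtype=int)

    meta = {
        "kind": "phantom",
        "electrode_mode": cfg.electrode_mode,
        "electrode_radius": cfg.electrode_radius,
        "scar_thickness": cfg.scar_thickness,
        "epithelium_center": cfg.epithelium_center.tolist(),
        "transversal_axis": cfg.transversal_axis.tolist(),
        "electrodes": [
            {"name": f"electrode_{k}", "role": role, "center": c.tolist()}
            for k, (role, c) in enumerate(electrodes)
        ],
        "bundles": {
            name: {
                "start": a.tolist(),
                "direction": u.tolist(),
                "length": cfg.nerve_length,
                "radius": cfg.nerve_radius,
            }
            for name, a, u in bundles
        },
    }
    return LabeledTetMesh(points, tets, region_id, region_names, fiber_axis, patches, meta)


def build_analytic_sphere(
    outer_radius: float = 35e-3,
    source_radius: float = 150e-6,
    resolution: float = 1.0,
    seed: int = 0,
) -> LabeledTetMesh:
    """Homogeneous sphere with a central spherical source electrode.

    Companion geometry for the closed-form point-source benchmark
    ``phi(r) = I/(4*pi*sigma) * (1/r - 1/R)``; one region ``medium``, one
    ``electrode_0`` patch at the center, grounded ``outer_boundary``.
    """
    rng = np.random.default_rng(seed)
    h0 = 55e-6 * resolution
    h_cap = 2.4e-3 * resolution

    def h_of_r(r):
        return min(h_cap, h0 + 0.35 * (r - source_radius))

    surf = [
        _sphere_points(np.zeros(3), source_radius, h0, rng),
        _sphere_points(np.zeros(3), outer_radius, h_cap * 0.9, rng),
    ]
    vol = _shell_cloud(
        np.zeros(3), source_radius + 0.8 * h0, outer_radius - 0.55 * h_cap, h_of_r, rng
    )
    points = np.vstack(surf + [vol])

    tri = Delaunay(points)
    tets, volumes = _orient_tets(points, tri.simplices)
    good = volumes > 1e-22
    tets = tets[good]
    centroids = points[tets].mean(axis=1)
    d_cent = np.linalg.norm(centroids, axis=1)
    d_max = np.linalg.norm(points[tets], axis=2).max(axis=1)
    region_id = np.full(len(tets), 2, dtype=int)
    inside = (d_cent < source_radius) & (d_max < source_radius * (1 + 1e-6))
    region_id[inside] = 1
    patches = {"electrode_0": _boundary_faces(tets, region_id == 1)}
    face_count = {}
    for t in range(len(tets)):
        for f in [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]:
            key = tuple(sorted(tets[t][list(f)]))
            face_count[key] = face_count.get(key, 0) + 1
    patches["outer_boundary"] = np.array(
        [k for k, c in face_count.items() if c == 1], dtype=int
    )
    meta = {
        "kind": "analytic_sphere",
        "electrode_radius": source_radius,
        "electrodes": [{"name": "electrode_0", "role": "source", "center": [0.0, 0.0, 0.0]}],
        "bundles": {},
    }
    return LabeledTetMesh(
        points, tets, region_id, {1: "electrode_0_region", 2: "medium"},
        np.zeros((len(tets), 3)), patches, meta,
    )


def place_electrodes(
    mesh: LabeledTetMesh,
    mode: str,
    epithelium_center=None,
    axis=None,
    areal_cdl: float = 15e-6,
    scar_thickness: float = 0.0,
) -> list[ElectrodeSpec]:
    """Electrode specifications for a stimulation mode, validated on a mesh.

    The phantom embeds its contacts at build time; this returns the matching
    specs (centers, roles, C_dl density, scar thickness) and checks that the
    requested mode is the one meshed and that the patches exist.  The
    reference role is always carried by the outer boundary.
    """
    meta = mesh.metadata
    if epithelium_center is None:
        epithelium_center = np.asarray(meta["epithelium_center"])
    if axis is None:
        axis = np.asarray(meta["transversal_axis"])
    wanted = electrode_positions(mode, epithelium_center, axis)
    embedded = meta.get("electrodes", [])
    if len(embedded) != len(wanted):
        raise ValueError(
            f"mesh embeds {len(embedded)} electrode(s); mode {mode!r} needs {len(wanted)}"
        )
    specs = []
    for k, ((role, center), emb) in enumerate(zip(wanted, embedded)):
        if not np.allclose(center, emb["center"], atol=1e-9):
            raise ValueError("mesh electrode positions do not match the requested mode")
        name = f"electrode_{k}"
        if name not in mesh.surface_patches or len(mesh.surface_patches[name]) == 0:
            raise ValueError(f"mesh lacks surface patch {name}")
        specs.append(
            ElectrodeSpec(
                name=name,
                center=center,
                radius=float(meta.get("electrode_radius", 150e-6)),
                role=role,
                areal_cdl=areal_cdl,
                scar_thickness=scar_thickness,
            )
        )
    return specs


def generate_fibers(
    mesh: LabeledTetMesh,
    branch: str,
    n: int = 400,
    type_mix: dict | None = None,
    seed: int = 0,
    n_nodes: int = 21,
    diameters: dict | None = None,
) -> list[FiberGeometry]:
    """Sample afferent fiber node chains inside one nerve bundle.

    Fibers run parallel to the bundle axis with a random radial offset and a
    small axial stagger; the internode length is 100x the outer fiber
    diameter (myelinated-fiber scaling).  Deterministic per seed.
    """
    if n <= 0:
        raise ValueError("fiber count must be positive")
    if branch not in mesh.metadata.get("bundles", {}):
        raise KeyError(f"unknown branch {branch!r}")
    info = mesh.metadata["bundles"][branch]
    a = np.asarray(info["start"])
    u = np.asarray(info["direction"])
    length, radius = info["length"], info["radius"]
    mix = dict(DEFAULT_TYPE_MIX if type_mix is None else type_mix)
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("type mix fractions must sum to 1")
    dia = dict(DEFAULT_DIAMETERS if diameters is None else diameters)

    rng = np.random.default_rng(seed)
    e1 = np.cross(u, [0.0, 0.0, 1.0] if abs(u[2]) < 0.9 else [1.0, 0.0, 0.0])
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(u, e1)

    types = rng.choice(list(mix.keys()), size=n, p=list(mix.values()))
    fibers = []
    margin = 0.15e-3
    for i in range(n):
        t = types[i]
        internode = 100.0 * dia[t]
        span = (n_nodes - 1) * internode
        s_max = length - margin - span
        if s_max <= margin:
            raise ValueError("bundle too short for the requested fiber chains")
        s0 = margin + rng.uniform(0.0, min(0.2e-3, s_max - margin))
        rr = (radius - margin) * np.sqrt(rng.random())
        th = rng.uniform(0, 2 * np.pi)
        offset = rr * (np.cos(th) * e1 + np.sin(th) * e2)
        nodes = a + offset + np.outer(s0 + internode * np.arange(n_nodes), u)
        fibers.append(FiberGeometry(i, branch, nodes, internode, dia[t], str(t)))
    return fibers


def fibers_to_table(fibers: list[FiberGeometry], path) -> None:
    """Write fiber node chains as tabular text."""
    with open(path, "w") as fh:
        fh.write("fiber_id\tbranch\tnode_index\tx_m\ty_m\tz_m\ttype\n")
        for f in fibers:
            for j, p in enumerate(f.node_positions):
                fh.write(
                    f"{f.fiber_id}\t{f.branch}\t{j}\t{p[0]:.17g}\t{p[1]:.17g}\t{p[2]:.17g}\t{f.afferent_type}\n"
                )


# ---------------------------------------------------------------------------
# mesh I/O: Gmsh MSH 2.2 ASCII and legacy VTK export

_MSH_TET = 4
_MSH_TRI = 2
_PATCH_TAG_BASE = 100


def write_mesh(mesh: LabeledTetMesh, path) -> None:
    """Write a labeled mesh as Gmsh MSH 2.2 ASCII.

    Regions become 3-D physical groups, surface patches 2-D physical groups;
    per-tet fiber axes go into an $ElementData block and phantom metadata
    into a vendor section ($VestfemMeta) that standard readers skip.
    Coordinates are written with 17 significant digits (bitwise round trip).
    """
    path = Path(path)
    patch_names = list(mesh.surface_patches)
    patch_tags = {n: _PATCH_TAG_BASE + i for i, n in enumerate(patch_names)}
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        fh.write("$PhysicalNames\n")
        fh.write(f"{len(mesh.region_names) + len(patch_names)}\n")
        for rid, name in sorted(mesh.region_names.items()):
            fh.write(f'3 {rid} "{name}"\n')
        for name in patch_names:
            fh.write(f'2 {patch_tags[name]} "{name}"\n')
        fh.write("$EndPhysicalNames\n$Nodes\n")
        fh.write(f"{mesh.n_vertices}\n")
        for i, (x, y, z) in enumerate(mesh.vertices, start=1):
            fh.write(f"{i} {x:.17g} {y:.17g} {z:.17g}\n")
        fh.write("$EndNodes\n$Elements\n")
        n_tris = sum(len(v) for v in mesh.surface_patches.values())
        fh.write(f"{mesh.n_tets + n_tris}\n")
        eid = 1
        for name in patch_names:
            tag = patch_tags[name]
            for tri in mesh.surface_patches[name]:
                fh.write(f"{eid} {_MSH_TRI} 2 {tag} {tag} "
                         f"{tri[0]+1} {tri[1]+1} {tri[2]+1}\n")
                eid += 1
        tet_eids = []
        for t in range(mesh.n_tets):
            a, b, c, d = mesh.tets[t] + 1
            rid = mesh.region_id[t]
            fh.write(f"{eid} {_MSH_TET} 2 {rid} {rid} {a} {b} {c} {d}\n")
            tet_eids.append(eid)
            eid += 1
        fh.write("$EndElements\n")
        nerve = np.flatnonzero(np.linalg.norm(mesh.fiber_axis, axis=1) > 0)
        if len(nerve):
            fh.write("$ElementData\n1\n\"fiber_axis\"\n1\n0\n3\n0\n3\n")
            fh.write(f"{len(nerve)}\n")
            for t in nerve:
                v = mesh.fiber_axis[t]
                fh.write(f"{tet_eids[t]} {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
            fh.write("$EndElementData\n")
        fh.write("$VestfemMeta\n")
        fh.write(json.dumps(mesh.metadata) + "\n")
        fh.write("$EndVestfemMeta\n")


def read_mesh(path) -> LabeledTetMesh:
    """Read a labeled mesh written by :func:`write_mesh` (Gmsh MSH 2.2)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    sections = {}
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("$") and not line.startswith("$End"):
            name = line[1:]
            j = i + 1
            while j < len(lines) and lines[j].strip() != f"$End{name}":
                j += 1
            sections[name] = lines[i + 1 : j]
            i = j + 1
        else:
            i += 1
    if "MeshFormat" not in sections or not sections["MeshFormat"][0].startswith("2.2"):
        raise ValueError("unsupported mesh format (expected Gmsh MSH 2.2 ASCII)")
    if "PhysicalNames" not in sections:
        raise ValueError("mesh file lacks region labels ($PhysicalNames)")

    region_names, patch_tags = {}, {}
    for line in sections["PhysicalNames"][1:]:
        parts = line.split(maxsplit=2)
        dim, tag, name = int(parts[0]), int(parts[1]), parts[2].strip('"')
        if dim == 3:
            region_names[tag] = name
        elif dim == 2:
            patch_tags[tag] = name

    node_lines = sections["Nodes"]
    n_nodes = int(node_lines[0])
    vertices = np.empty((n_nodes, 3))
    for line in node_lines[1 : 1 + n_nodes]:
        parts = line.split()
        vertices[int(parts[0]) - 1] = [float(parts[1]), float(parts[2]), float(parts[3])]

    tets, region_id, patches = [], [], {name: [] for name in patch_tags.values()}
    eid_to_tet = {}
    for line in sections["Elements"][1:]:
        parts = [int(p) for p in line.split()]
        eid, etype, ntags = parts[0], parts[1], parts[2]
        tags = parts[3 : 3 + ntags]
        nodes = [p - 1 for p in parts[3 + ntags :]]
        if etype == _MSH_TET:
            if not tags or tags[0] not in region_names:
                raise ValueError(f"tetrahedron {eid} has no known region label")
            eid_to_tet[eid] = len(tets)
            tets.append(nodes)
            region_id.append(tags[0])
        elif etype == _MSH_TRI:
            if tags and tags[0] in patch_tags:
                patches[patch_tags[tags[0]]].append(nodes)
    tets = np.array(tets, dtype=int)
    region_id = np.array(region_id, dtype=int)
    fiber_axis = np.zeros((len(tets), 3))
    if "ElementData" in sections:
        data = sections["ElementData"]
        # header: 1 string tag, 1 real tag, 4 int tags (time step, comps, count)
        idx = 1 + int(data[0])
        idx += 1 + int(data[idx])
        n_int = int(data[idx])
        ints = [int(data[idx + 1 + k]) for k in range(n_int)]
        count = ints[2] if len(ints) >= 3 else ints[-1]
        start = idx + 1 + n_int
        for line in data[start : start + count]:
            parts = line.split()
            fiber_axis[eid_to_tet[int(parts[0])]] = [float(p) for p in parts[1:4]]
    metadata = {}
    if "VestfemMeta" in sections:
        metadata = json.loads("\n".join(sections["VestfemMeta"]))
    patches = {k: np.array(v, dtype=int) if v else np.empty((0, 3), dtype=int)
               for k, v in patches.items()}
    return LabeledTetMesh(vertices, tets, region_id, region_names, fiber_axis, patches, metadata)


def write_vtk(mesh: LabeledTetMesh, path, cell_scalars: dict | None = None) -> None:
    """Export to legacy ASCII VTK unstructured grid (for external viewers)."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nvestfem phantom\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for x, y, z in mesh.vertices:
            fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
        fh.write(f"CELLS {mesh.n_tets} {5 * mesh.n_tets}\n")
        for t in mesh.tets:
            fh.write(f"4 {t[0]} {t[1]} {t[2]} {t[3]}\n")
        fh.write(f"CELL_TYPES {mesh.n_tets}\n")
        fh.write("\n".join(["10"] * mesh.n_tets) + "\n")
        fh.write(f"CELL_DATA {mesh.n_tets}\n")
        fh.write("SCALARS region_id int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(r) for r in mesh.region_id) + "\n")
        for name, vals in (cell_scalars or {}).items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(f"{v:.9g}" for v in vals) + "\n")
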
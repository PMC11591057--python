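"""Synthetic layered head geometry.

Concentric icosphere shells stand in for MRI-derived head surfaces: a
five-layer skin/skull/CSF/GM/WM stack, or the coarse three-layer
SKIN/SKULL/BRAIN stack used by the classical potential-based inverse model.
Dipoles are placed on the midsurface between the CSF-GM and GM-WM
interfaces with orientations normal to the CSF-GM interface; electrodes are
placed quasi-uniformly on the skin and snapped to mesh facets.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import trimesh
from scipy.spatial import cKDTree

__all__ = [
    "TriMesh",
    "LayeredHeadModel",
    "ElectrodeArray",
    "CONDUCTIVITY_PRESETS",
    "make_icosphere",
    "make_layered_sphere_model",
    "place_midsurface_dipoles",
    "place_dipoles_kmeans",
    "place_electrodes",
]

# Per-tissue conductivities (S/m).  The seven-compartment sets carry the
# cerebellum/ventricle/eye values of their sources even though the synthetic
# shell geometry only uses the five main layers; the three-layer sets are the
# matched SKIN/SKULL/BRAIN values used by the inverse model.
CONDUCTIVITY_PRESETS = {
    "VWB7": {
        "skin": 0.430, "skull": 0.010, "csf": 1.790, "gm": 0.330,
        "wm": 0.140, "cerebellum": 0.216, "ventricles": 1.790, "eyes": 1.790,
    },
    "IT'IS7": {
        "skin": 0.147, "skull": 0.0179, "csf": 1.880, "gm": 0.419,
        "wm": 0.348, "cerebellum": 0.577, "ventricles": 1.880, "eyes": 1.880,
    },
    "SimNIBS7": {
        "skin": 0.465, "skull": 0.010, "csf": 1.654, "gm": 0.275,
        "wm": 0.126, "cerebellum": 0.126, "ventricles": 1.654, "eyes": 1.654,
    },
    "VWB3": {"skin": 0.430, "skull": 0.010, "brain": 0.330},
    "IT'IS3": {"skin": 0.147, "skull": 0.0179, "brain": 0.375},
    "SimNIBS3": {"skin": 0.465, "skull": 0.010, "brain": 0.330},
}

# Layer -> tissue key, by number of nested surfaces.
_LAYER_TISSUES = {
    5: ("skin", "skull", "csf", "gm", "wm"),
    4: ("skin", "skull", "csf", "gm"),
    3: ("skin", "skull", "brain"),
}


@dataclasses.dataclass
class TriMesh:
    """Closed triangulated surface with per-facet centers, outward normals
    and areas (meters)."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(cross, axis=1)
        if np.any(norm <= 0):
            raise ValueError("mesh contains degenerate (zero-area) facets")
        self.triangles = tri
        self.centers = tri.mean(axis=1)
        self.normals = cross / norm[:, None]
        self.areas = 0.5 * norm

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh) -> "TriMesh":
        mesh = mesh.copy()
        if mesh.volume < 0:
            mesh.invert()
        return cls(np.asarray(mesh.vertices), np.asarray(mesh.faces))

    @property
    def volume(self) -> float:
        """Enclosed signed volume by the divergence theorem."""
        return float(np.einsum("ij,ij->", self.centers, self.normals * self.areas[:, None]) / 3.0)

    @property
    def area(self) -> float:
        return float(self.areas.sum())

    def is_closed(self) -> bool:
        return bool(self.as_trimesh().is_watertight)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Ray-casting parity test for point containment (odd number of
        ray-triangle crossings = inside)."""
        return _ray_parity_contains(self.triangles, np.atleast_2d(points))

    def closest_points(self, points: np.ndarray) -> np.ndarray:
        """Closest point on the surface for each query point (candidate
        facets from a KD-tree over centroids, exact point-triangle
        projection on the candidates)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        tree = cKDTree(self.centers)
        k = min(12, self.n_faces)
        _, cand = tree.query(points, k=k)
        cand = np.atleast_2d(cand)
        out = np.empty_like(points)
        for i, p in enumerate(points):
            tri = self.triangles[cand[i]]
            proj = trimesh.triangles.closest_point(tri, np.tile(p, (len(tri), 1)))
            d = np.linalg.norm(proj - p, axis=1)
            out[i] = proj[np.argmin(d)]
        return out


def _ray_parity_contains(triangles: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Vectorized Moeller-Trumbore parity test along a fixed irrational ray
    direction (re-cast along a different direction on near-degenerate hits)."""
    directions = np.array([
        [0.57735026918962573, 0.57735026918962584, 0.57735026918962595],
        [0.26726124191242440, 0.53452248382484879, 0.80178372573727319],
        [0.80178372573727319, -0.26726124191242440, 0.53452248382484879],
    ])
    v0 = triangles[:, 0]
    e1 = triangles[:, 1] - v0
    e2 = triangles[:, 2] - v0
    result = np.zeros(len(points), dtype=bool)
    pending = np.arange(len(points))
    eps = 1e-12
    for d in directions:
        if len(pending) == 0:
            break
        h = np.cross(d, e2)
        a = np.einsum("ij,ij->i", e1, h)
        ok = np.abs(a) > eps
        inv_a = np.where(ok, 1.0 / np.where(ok, a, 1.0), 0.0)
        still_pending = []
        for idx in pending:
            p = points[idx]
            s = p - v0
            u = np.einsum("ij,ij->i", s, h) * inv_a
            q = np.cross(s, e1)
            v = np.einsum("j,ij->i", d, q) * inv_a
            t = np.einsum("ij,ij->i", e2, q) * inv_a
            hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 0)
            margin = 1e-9
            degenerate = hit & ((u < margin) | (v < margin)
                                | (u + v > 1 - margin) | (t < margin))
            if degenerate.any():
                still_pending.append(idx)
                continue
            result[idx] = bool(hit.sum() % 2)
        pending = np.array(still_pending, dtype=int)
    if len(pending):  # all retry directions degenerate: accept last parity
        for idx in pending:
            p = points[idx]
            s = p - v0
            u = np.einsum("ij,ij->i", s, h) * inv_a
            q = np.cross(s, e1)
            v = np.einsum("j,ij->i", directions[-1], q) * inv_a
            t = np.einsum("ij,ij->i", e2, q) * inv_a
            hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 0)
            result[idx] = bool(hit.sum() % 2)
    return result


def make_icosphere(radius: float, subdivisions: int) -> TriMesh:
    """Icosahedron-based sphere mesh with 20 * 4**subdivisions facets."""
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if subdivisions < 0 or int(subdivisions) != subdivisions:
        raise ValueError(f"subdivisions must be a non-negative integer, got {subdivisions}")
    mesh = trimesh.creation.icosphere(subdivisions=int(subdivisions), radius=radius)
    return TriMesh.from_trimesh(mesh)


@dataclasses.dataclass
class LayeredHeadModel:
    """Ordered nested closed surfaces with per-compartment conductivities.

    ``surfaces`` are ordered outermost to innermost; ``conductivities[i]`` is
    the conductivity of the compartment directly inside ``surfaces[i]``.  The
    medium outside the outermost surface is vacuum (sigma = 0).
    ``source_conductivity`` is the conductivity of the medium the dipole sits
    in (grey matter for five-layer models, BRAIN for three-layer ones).
    """

    surfaces: list
    conductivities: np.ndarray
    names: tuple = ()
    source_conductivity: float = None
    preset: str = ""

    def __post_init__(self):
        self.conductivities = np.asarray(self.conductivities, dtype=float)
        if len(self.surfaces) != len(self.conductivities):
            raise ValueError("one conductivity per surface required")
        if np.any(self.conductivities <= 0):
            raise ValueError("conductivities must be positive")
        if not self.names:
            self.names = tuple(f"layer{i}" for i in range(len(self.surfaces)))
        if self.source_conductivity is None:
            self.source_conductivity = float(self.conductivities[-1])

    @property
    def n_layers(self) -> int:
        return len(self.surfaces)

    def sigma_inner_outer(self):
        """(sigma-, sigma+) per surface: conductivity just inside / outside."""
        sig_in = self.conductivities
        sig_out = np.concatenate([[0.0], self.conductivities[:-1]])
        return sig_in, sig_out

    def contrasts(self) -> np.ndarray:
        """Conductivity contrast K = (sigma- - sigma+)/(sigma- + sigma+)
        per surface."""
        sig_in, sig_out = self.sigma_inner_outer()
        return (sig_in - sig_out) / (sig_in + sig_out)

    def validate_nesting(self):
        """Exact ray-parity nesting check: every vertex of surface i+1 must
        lie inside surface i."""
        for outer, inner in zip(self.surfaces[:-1], self.surfaces[1:]):
            if not outer.contains(inner.vertices).all():
                raise ValueError("surfaces are not strictly nested")


def make_layered_sphere_model(radii, preset=None, subdivisions=4,
                              conductivities=None, names=None) -> LayeredHeadModel:
    """Concentric-sphere head model.

    Parameters
    ----------
    radii : descending outer radii of the shells (m).
    preset : conductivity-set name (e.g. ``"SimNIBS7"``); alternatively pass
        explicit per-compartment ``conductivities``.
    subdivisions : icosphere subdivision level, scalar or one per layer.
    """
    radii = np.asarray(radii, dtype=float)
    if np.any(np.diff(radii) >= 0) or np.any(radii <= 0):
        raise ValueError("radii must be positive and strictly decreasing")
    n = len(radii)
    subs = np.broadcast_to(np.asarray(subdivisions, dtype=int), (n,))
    if conductivities is None:
        if preset is None:
            raise ValueError("either preset or conductivities is required")
        key = preset.replace("ITIS", "IT'IS")
        if key not in CONDUCTIVITY_PRESETS:
            raise KeyError(
                f"unknown conductivity preset {preset!r}; "
                f"choose from {sorted(CONDUCTIVITY_PRESETS)}")
        if n not in _LAYER_TISSUES:
            raise ValueError(f"presets define {sorted(_LAYER_TISSUES)}-layer models, got {n}")
        tissues = _LAYER_TISSUES[n]
        table = CONDUCTIVITY_PRESETS[key]
        conductivities = [table[t] for t in tissues]
        names = tissues
        source = table.get("gm", table.get("brain"))
    else:
        source = None
        key = preset or ""
    surfaces = [make_icosphere(r, s) for r, s in zip(radii, subs)]
    return LayeredHeadModel(surfaces, conductivities, names=tuple(names or ()),
                            source_conductivity=source, preset=key)


def place_midsurface_dipoles(gm_surface: TriMesh, wm_surface: TriMesh,
                             n: int, seed: int):
    """Dipole positions midway between the CSF-GM and GM-WM interfaces,
    oriented along the outward normal of the nearest CSF-GM facet.

    Returns (positions (n,3), orientations (n,3)).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    _check_nested(gm_surface, wm_surface)
    rng = np.random.default_rng(seed)
    weights = gm_surface.areas / gm_surface.areas.sum()
    replace = n > gm_surface.n_faces
    idx = rng.choice(gm_surface.n_faces, size=n, replace=replace, p=weights)
    anchors = gm_surface.centers[idx]
    closest = wm_surface.closest_points(anchors)
    positions = 0.5 * (anchors + closest)
    orientations = gm_surface.normals[idx]
    return positions, orientations


def _check_nested(outer: TriMesh, inner: TriMesh):
    if not outer.contains(inner.vertices).all():
        raise ValueError("inner surface is not nested inside outer surface")


def place_dipoles_kmeans(surface: TriMesh, k: int, seed: int) -> np.ndarray:
    """Well-separated positions: k-means over facet centers, each cluster
    center snapped to the nearest facet center."""
    from sklearn.cluster import KMeans

    if k > surface.n_faces:
        raise ValueError(f"k={k} exceeds facet count {surface.n_faces}")
    km = KMeans(n_clusters=k, random_state=int(seed) % (2**31), n_init=1)
    km.fit(surface.centers)
    tree = cKDTree(surface.centers)
    _, nearest = tree.query(km.cluster_centers_)
    return surface.centers[nearest]


@dataclasses.dataclass
class ElectrodeArray:
    """Electrodes snapped to skin facets; positions are the assigned facet
    centers, so the nearest-facet invariant holds exactly."""

    positions: np.ndarray
    facet_index: np.ndarray
    labels: tuple = ()

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.facet_index = np.asarray(self.facet_index, dtype=np.int64)
        if not self.labels:
            self.labels = tuple(f"E{i + 1:03d}" for i in range(len(self.facet_index)))

    @property
    def n(self) -> int:
        return len(self.facet_index)


def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    golden = (1 + 5**0.5) / 2
    z = 1 - (2 * i + 1) / n
    phi = 2 * np.pi * i / golden
    s = np.sqrt(1 - z * z)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def place_electrodes(skin: TriMesh, n: int) -> ElectrodeArray:
    """Quasi-uniform electrode montage: Fibonacci lattice on the bounding
    sphere, each point assigned to the nearest skin facet (distinct facets)."""
    if n < 4:
        raise ValueError("at least 4 electrodes required")
    if not skin.is_closed():
        raise ValueError("skin mesh must be closed")
    center = skin.vertices.mean(axis=0)
    radius = np.linalg.norm(skin.vertices - center, axis=1).max()
    points = center + radius * _fibonacci_directions(n)
    tree = cKDTree(skin.centers)
    k_query = min(max(8, 4 * n // skin.n_faces + 8), skin.n_faces)
    _, candidates = tree.query(points, k=k_query)
    candidates = np.atleast_2d(candidates)
    used = set()
    facet_index = np.empty(n, dtype=np.int64)
    for i in range(n):
        for c in candidates[i]:
            if c not in used:
                used.add(int(c))
                facet_index[i] = c
                break
        else:
            raise ValueError("could not assign distinct facets to all electrodes")
    return ElectrodeArray(skin.centers[facet_index], facet_index)
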
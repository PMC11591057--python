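"""Charge-based BEM forward solver.

The unknown is the induced surface charge density rho on every conductivity
interface.  With centroid collocation and a piecewise-constant charge basis,
the m-th facet equation reads

    rho_m/(2 eps0) - K_m n_m . sum_{n != m} rho_n A_n (r_m - r_n) /
        (4 pi eps0 |r_m - r_n|^3)  =  K_m E_i(r_m) . n_m

where K is the conductivity contrast across the facet's interface.  The
system is solved with restarted GMRES; the code works internally with the
diagonally scaled form (multiplied by 2 eps0) whose diagonal is one.

Total potentials are recovered from the single-layer sum
phi = phi_i + sum_n rho_n A_n / (4 pi eps0 |r - r_n|); evaluation at a facet
center replaces that facet's term by the analytic constant-charge
self-integral.  Electrode voltages are the potentials at the skin facets the
electrodes are assigned to.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.constants
import scipy.sparse.linalg

from . import _kernels
from .geometry import ElectrodeArray, LayeredHeadModel
from .sources import CurrentDipole, impressed_efield, impressed_potential

EPS0 = scipy.constants.epsilon_0

__all__ = ["BemSystem", "ChargeSolution", "EEGSample", "apply_operator",
           "solve_charges", "surface_potential", "electrode_voltages", "EPS0"]

# Largest facet count for which the dense operator matrix is assembled
# (memory: M^2 float64); above this GMRES falls back to the on-the-fly
# matvec kernel.
DENSE_LIMIT = 26000

# Facet pairs closer than this multiple of the larger panel size use
# subdivided-panel quadrature of the field integral instead of the
# point-panel (centroid) kernel.  The thin head compartments put adjacent
# interfaces within about one panel size of each other at working
# resolutions, where the centroid kernel is the dominant error source.
NEAR_FIELD_FACTOR = 3.0


def _near_pairs(system: "BemSystem", factor: float, subset=None):
    """Ordered near pairs (rows, cols): |r_m - r_n| <= factor * max panel
    size of the pair.  With ``subset``, only pairs involving those facet
    indices (in either role) are returned."""
    from scipy.spatial import cKDTree
    sizes = np.sqrt(system.areas)
    radius = factor * sizes.max()
    centers = system.centers
    tree = cKDTree(centers)
    if subset is None:
        pairs = tree.query_pairs(r=radius, output_type="ndarray")
        if len(pairs) == 0:
            return (np.empty(0, dtype=np.int64),) * 2
        rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
        cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
    else:
        subset = np.asarray(subset, dtype=np.int64)
        neighbor_lists = tree.query_ball_point(centers[subset], r=radius)
        rows_l, cols_l = [], []
        for c, neigh in zip(subset, neighbor_lists):
            neigh = np.asarray(neigh, dtype=np.int64)
            neigh = neigh[neigh != c]
            rows_l.append(np.full(len(neigh), c, dtype=np.int64))
            cols_l.append(neigh)
        rows = np.concatenate([*rows_l, *cols_l])
        cols = np.concatenate([*cols_l, *rows_l])
        # drop duplicate subset-subset pairs counted in both roles
        key = rows * system.n_facets + cols
        _, unique_idx = np.unique(key, return_index=True)
        rows, cols = rows[unique_idx], cols[unique_idx]
    d = np.linalg.norm(centers[rows] - centers[cols], axis=1)
    keep = d <= factor * np.maximum(sizes[rows], sizes[cols])
    return rows[keep], cols[keep]


def _apply_near_field(matrix: np.ndarray, system: "BemSystem", factor,
                      subset=None):
    if not factor:
        return
    rows, cols = _near_pairs(system, factor, subset=subset)
    if len(rows) == 0:
        return
    vals = _kernels.near_field_entries(system.triangles, system.centers,
                                       system.normals, system.areas,
                                       system.contrast, rows, cols,
                                       _kernels.QUAD_BARY)
    matrix[rows, cols] = vals


@dataclasses.dataclass
class BemSystem:
    """Concatenated facet data over all interfaces of a layered model.

    Facets are grouped by surface, outermost surface first, so skin facet
    indices are stable under refinement of the inner layers.
    """

    triangles: np.ndarray   # (M, 3, 3) facet corner coordinates
    contrast: np.ndarray    # (M,) conductivity contrast K
    surface_id: np.ndarray  # (M,) index of the owning surface
    n_surfaces: int
    sigma_src: float        # conductivity of the dipole's medium
    skin_surface: int = 0

    def __post_init__(self):
        tri = np.ascontiguousarray(self.triangles, dtype=float)
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(cross, axis=1)
        self.triangles = tri
        self.centers = np.ascontiguousarray(tri.mean(axis=1))
        self.normals = np.ascontiguousarray(cross / norm[:, None])
        self.areas = np.ascontiguousarray(0.5 * norm)
        self.contrast = np.ascontiguousarray(self.contrast, dtype=float)
        if np.any(np.abs(self.contrast) > 1):
            raise ValueError("conductivity contrast must lie in [-1, 1]")
        self.surface_id = np.ascontiguousarray(self.surface_id, dtype=np.int64)
        self._self_integral = None

    @property
    def n_facets(self) -> int:
        return len(self.areas)

    @classmethod
    def from_model(cls, model: LayeredHeadModel,
                   outer_conductivity: float = 0.0) -> "BemSystem":
        """Concatenate the model's surfaces into one facet system.

        ``outer_conductivity`` is the conductivity of the medium outside the
        outermost surface (0 = air).  Setting it equal to the skin
        conductivity realizes the homogeneous-medium null case (all contrasts
        vanish and the impressed field is the whole solution).
        """
        sig_in, sig_out = model.sigma_inner_outer()
        sig_out = sig_out.copy()
        sig_out[0] = outer_conductivity
        contrasts = (sig_in - sig_out) / (sig_in + sig_out)
        tris, ks, sid = [], [], []
        for i, surf in enumerate(model.surfaces):
            tris.append(surf.triangles)
            ks.append(np.full(surf.n_faces, contrasts[i]))
            sid.append(np.full(surf.n_faces, i, dtype=np.int64))
        return cls(np.concatenate(tris), np.concatenate(ks), np.concatenate(sid),
                   n_surfaces=model.n_layers, sigma_src=model.source_conductivity)

    def surface_slice(self, i: int) -> slice:
        idx = np.flatnonzero(self.surface_id == i)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def self_integrals(self) -> np.ndarray:
        """Analytic integral of 1/|r_c - r'| over each facet from its own
        centroid (used for on-facet potential evaluation)."""
        if self._self_integral is None:
            self._self_integral = _centroid_self_integral(self.triangles)
        return self._self_integral


def _centroid_self_integral(triangles: np.ndarray) -> np.ndarray:
    """integral over the triangle of dA/|c - r'| with c the centroid.

    Per edge, with p the in-plane observation point, h the distance from p to
    the edge line and t the signed coordinate along the edge, the contribution
    is h * (asinh(t2/h) - asinh(t1/h)).
    """
    c = triangles.mean(axis=1)
    total = np.zeros(len(triangles))
    for a, b in ((0, 1), (1, 2), (2, 0)):
        v1 = triangles[:, a]
        v2 = triangles[:, b]
        edge = v2 - v1
        length = np.linalg.norm(edge, axis=1)
        u = edge / length[:, None]
        w = v1 - c
        t1 = np.einsum("ij,ij->i", w, u)
        t2 = t1 + length
        perp = w - t1[:, None] * u
        h = np.linalg.norm(perp, axis=1)
        total += h * (np.arcsinh(t2 / h) - np.arcsinh(t1 / h))
    return total


@dataclasses.dataclass
class ChargeSolution:
    """Per-facet surface charge density (C/m^2) with solver diagnostics."""

    rho: np.ndarray
    residual_norm: float
    iterations: int
    method: str = "gmres"

    @property
    def converged(self) -> bool:
        return np.isfinite(self.residual_norm)


def _scaled_rhs(system: BemSystem, dipole: CurrentDipole) -> np.ndarray:
    ei = impressed_efield(dipole, system.centers, system.sigma_src)
    return 2 * EPS0 * system.contrast * np.einsum("ij,ij->i", ei, system.normals)


def _row_weights(system: BemSystem) -> np.ndarray:
    """Galerkin-consistent area weights: each facet's collocation equation is
    weighted by its relative area, so the GMRES residual approximates the L2
    norm of the residual function.  On locally refined meshes (panel areas
    spanning orders of magnitude) the unweighted residual is dominated by the
    tiny near-source panels and stops controlling the electrode voltages.
    The solvers apply the weights as a diagonal similarity transform
    D A D^-1 (y = D rho), which keeps the operator's eigenvalues, and hence
    GMRES convergence, unchanged."""
    return system.areas / system.areas.mean()


def apply_operator(system: BemSystem, rho: np.ndarray) -> np.ndarray:
    """Left-hand side of the collocation equation (V/m) for a given charge
    density: rho_m/(2 eps0) - K_m n_m . sum_{n!=m} rho_n A_n (r_m-r_n)/
    (4 pi eps0 |r_m-r_n|^3)."""
    rho = np.ascontiguousarray(rho, dtype=float)
    if rho.shape != (system.n_facets,):
        raise ValueError("rho length must equal the facet count")
    _check_distinct_centers(system)
    return _kernels.charge_matvec(system.centers, system.normals, system.areas,
                                  system.contrast, rho) / (2 * EPS0)


def _check_distinct_centers(system: BemSystem):
    # Coincident collocation points across surfaces make the kernel singular.
    tree_min = None
    if system.n_facets < 2:
        return
    from scipy.spatial import cKDTree
    tree_min = cKDTree(system.centers).query(system.centers, k=2)[0][:, 1].min()
    if tree_min == 0.0:
        raise ValueError("coincident facet centers in the BEM system")


def _near_field_delta(system: BemSystem, factor):
    """Sparse correction (exact near entries minus centroid entries) added to
    the on-the-fly matvec so that all solve paths share one operator."""
    import scipy.sparse
    m_tot = system.n_facets
    if not factor:
        return scipy.sparse.csr_matrix((m_tot, m_tot))
    rows, cols = _near_pairs(system, factor)
    if len(rows) == 0:
        return scipy.sparse.csr_matrix((m_tot, m_tot))
    exact = _kernels.near_field_entries(system.triangles, system.centers,
                                        system.normals, system.areas,
                                        system.contrast, rows, cols,
                                        _kernels.QUAD_BARY)
    d = system.centers[rows] - system.centers[cols]
    r3 = np.linalg.norm(d, axis=1) ** 3
    centroid = (-system.contrast[rows] / (2 * np.pi) * system.areas[cols]
                * np.einsum("ij,ij->i", system.normals[rows], d) / r3)
    return scipy.sparse.csr_matrix((exact - centroid, (rows, cols)),
                                   shape=(m_tot, m_tot))


def solve_charges(system: BemSystem, dipole: CurrentDipole, tol: float = 1e-5,
                  method: str = "auto", restart: int = 300, maxiter: int = 300,
                  dense_limit: int = DENSE_LIMIT,
                  near_field: float = NEAR_FIELD_FACTOR) -> ChargeSolution:
    """Solve the charge integral equation for ``dipole``.

    ``tol`` is the relative GMRES residual.  ``method``:
    ``"auto"`` assembles the dense operator when it fits in memory and runs
    GMRES on it; ``"matvec"`` forces the on-the-fly kernel; ``"direct"``
    does a dense LU solve (reference path for oracle-equivalence tests).
    ``near_field`` sets the radius factor for quadrature-corrected near-pair
    entries (0/None keeps the pure point-panel collocation kernel).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    m_tot = system.n_facets
    b = _scaled_rhs(system, dipole)
    b_norm = np.linalg.norm(b)
    if b_norm == 0.0:
        return ChargeSolution(np.zeros(m_tot), 0.0, 0, method="trivial")

    if method == "direct" or (method == "auto" and m_tot <= 600):
        mat = DenseOperator(system, near_field=near_field).matrix
        rho = np.linalg.solve(mat, b)
        res = np.linalg.norm(mat @ rho - b) / b_norm
        return ChargeSolution(rho, float(res), 1, method="direct")

    counter = _IterationCounter()
    w = _row_weights(system)
    bw = w * b
    bw_norm = np.linalg.norm(bw)
    if method == "matvec" or m_tot > dense_limit:
        delta = _near_field_delta(system, near_field)

        def matvec(y):
            x = np.ascontiguousarray(y / w)
            return w * (_kernels.charge_matvec(system.centers, system.normals,
                                               system.areas, system.contrast,
                                               x) + delta @ x)

        used = "gmres-matvec"
    else:
        mat = DenseOperator(system, near_field=near_field).matrix

        def matvec(y):
            return w * (mat @ (y / w))

        used = "gmres-dense"
    op = scipy.sparse.linalg.LinearOperator((m_tot, m_tot), matvec=matvec)
    y, info = scipy.sparse.linalg.gmres(
        op, bw, rtol=tol, atol=0.0, restart=min(restart, maxiter),
        maxiter=max(1, -(-maxiter // restart)), callback=counter,
        callback_type="pr_norm")
    rho = y / w
    res = np.linalg.norm(op @ (w * rho) - bw) / bw_norm
    if info != 0 and res > tol:
        raise RuntimeError(
            f"GMRES failed to converge: relative residual {res:.3e} "
            f"after {counter.count} iterations (tol {tol:.1e})")
    return ChargeSolution(rho, float(res), counter.count, method=used)


class _IterationCounter:
    def __init__(self):
        self.count = 0

    def __call__(self, _):
        self.count += 1


class DenseOperator:
    """Dense scaled charge operator maintained incrementally across mesh
    refinement.

    The matrix lives in a preallocated capacity buffer; refinement overwrites
    each subdivided parent's slot with its first child and appends the other
    three children at the end, so rows/columns of untouched facets stay valid
    and only the changed indices are recomputed.
    """

    def __init__(self, system: BemSystem, capacity: int = 0,
                 near_field: float = NEAR_FIELD_FACTOR):
        self.system = system
        self.near_field = near_field
        m = system.n_facets
        self._cap = max(capacity, m)
        # flat buffer whose contiguous prefix holds the current (m, m) matrix,
        # so BLAS sees a plain C-contiguous operand
        self._buf = np.empty(self._cap * self._cap)
        self._m = m
        _kernels.charge_rows_into(system.centers, system.normals, system.areas,
                                  system.contrast, np.arange(m, dtype=np.int64),
                                  self.matrix)
        _apply_near_field(self.matrix, system, near_field)

    @property
    def matrix(self) -> np.ndarray:
        return self._buf[:self._m * self._m].reshape(self._m, self._m)

    @property
    def n_facets(self) -> int:
        return self._m

    def clone(self, capacity: int = 0) -> "DenseOperator":
        """Copy of the assembled operator (used to reuse one base-mesh
        assembly across several per-dipole refinement runs)."""
        other = object.__new__(DenseOperator)
        other.system = self.system
        other.near_field = self.near_field
        other._m = self._m
        other._cap = max(capacity, self._m)
        other._buf = np.empty(other._cap * other._cap)
        other._buf[:self._m * self._m] = self._buf[:self._m * self._m]
        return other

    def reassemble(self, system: BemSystem):
        """Assemble ``system``'s operator into the existing buffer (reusing
        already-faulted pages is cheaper than reallocating across per-dipole
        refinement runs)."""
        m = system.n_facets
        if self._cap < m:
            self._buf = None
            self._cap = m
            self._buf = np.empty(self._cap * self._cap)
        self._m = m
        self.system = system
        _kernels.charge_rows_into(system.centers, system.normals, system.areas,
                                  system.contrast, np.arange(m, dtype=np.int64),
                                  self.matrix)
        _apply_near_field(self.matrix, system, self.near_field)

    def update(self, system: BemSystem, changed_idx: np.ndarray):
        """Adopt a refined system; ``changed_idx`` are the facet indices whose
        geometry is new (overwritten parent slots plus the appended tail)."""
        m_old, m = self._m, system.n_facets
        self.system = system
        if m > self._cap:
            # outgrew the buffer: drop it and reassemble at the new size
            self._buf = None
            self._cap = int(m * 1.1)
            self._buf = np.empty(self._cap * self._cap)
            self._m = m
            _kernels.charge_rows_into(system.centers, system.normals,
                                      system.areas, system.contrast,
                                      np.arange(m, dtype=np.int64), self.matrix)
            _apply_near_field(self.matrix, system, self.near_field)
            return
        _kernels.repack_rows(self._buf, m_old, m)
        self._m = m
        idx = np.ascontiguousarray(changed_idx, dtype=np.int64)
        _kernels.charge_rows_into(system.centers, system.normals, system.areas,
                                  system.contrast, idx, self.matrix)
        _kernels.charge_cols_into(system.centers, system.normals, system.areas,
                                  system.contrast, idx, self.matrix)
        _apply_near_field(self.matrix, system, self.near_field, subset=idx)

    def solve(self, dipole: CurrentDipole, tol: float = 1e-5, x0=None,
              restart: int = 300, maxiter: int = 300) -> ChargeSolution:
        b = _scaled_rhs(self.system, dipole)
        if np.linalg.norm(b) == 0.0:
            return ChargeSolution(np.zeros(self._m), 0.0, 0, method="trivial")
        counter = _IterationCounter()
        w = _row_weights(self.system)
        mat = self.matrix

        def matvec(y):
            return w * (mat @ (y / w))

        op = scipy.sparse.linalg.LinearOperator((self._m, self._m), matvec=matvec)
        bw = w * b
        bw_norm = np.linalg.norm(bw)
        y0 = None if x0 is None else w * x0
        y, info = scipy.sparse.linalg.gmres(
            op, bw, x0=y0, rtol=tol, atol=0.0,
            restart=min(restart, maxiter), maxiter=max(1, -(-maxiter // restart)),
            callback=counter, callback_type="pr_norm")
        rho = y / w
        res = np.linalg.norm(w * (mat @ rho) - bw) / bw_norm
        if info != 0 and res > tol:
            raise RuntimeError(
                f"GMRES failed to converge: relative residual {res:.3e} "
                f"after {counter.count} iterations (tol {tol:.1e})")
        return ChargeSolution(rho, float(res), counter.count, method="gmres-dense")


def surface_potential(system: BemSystem, solution: ChargeSolution,
                      dipole: CurrentDipole, points, self_index=None) -> np.ndarray:
    """Total potential phi = phi_i + single-layer charge potential (V).

    ``self_index[i]`` gives the facet whose centroid equals ``points[i]``
    (its contribution uses the analytic self-integral); -1 or None for
    off-surface points.
    """
    points = np.ascontiguousarray(np.atleast_2d(points), dtype=float)
    if self_index is None:
        self_index = np.full(len(points), -1, dtype=np.int64)
    else:
        self_index = np.ascontiguousarray(self_index, dtype=np.int64)
    phi = impressed_potential(dipole, points, system.sigma_src)
    lay = _kernels.single_layer_sum(system.centers, system.areas,
                                    np.ascontiguousarray(solution.rho, dtype=float),
                                    points, self_index)
    phi = phi + lay / (4 * np.pi * EPS0)
    on_facet = self_index >= 0
    if np.any(on_facet):
        ints = system.self_integrals()
        phi[on_facet] += (solution.rho[self_index[on_facet]]
                          * ints[self_index[on_facet]] / (4 * np.pi * EPS0))
    return phi


@dataclasses.dataclass
class EEGSample:
    """Single-time-sample electrode voltages with reference metadata."""

    voltages: np.ndarray
    labels: tuple
    reference: str = "raw"
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.voltages = np.asarray(self.voltages, dtype=float)

    def average_referenced(self) -> "EEGSample":
        return EEGSample(self.voltages - self.voltages.mean(), self.labels,
                         reference="average", meta=dict(self.meta))


def electrode_voltages(system: BemSystem, solution: ChargeSolution,
                       dipole: CurrentDipole, electrodes: ElectrodeArray) -> EEGSample:
    """Potential at each electrode's assigned skin facet center."""
    skin = system.surface_slice(system.skin_surface)
    n_skin = skin.stop - skin.start
    if np.any(electrodes.facet_index < 0) or np.any(electrodes.facet_index >= n_skin):
        raise IndexError("electrode facet index out of range for the skin surface")
    idx = electrodes.facet_index + skin.start
    points = system.centers[idx]
    v = surface_potential(system, solution, dipole, points, self_index=idx)
    return EEGSample(v, electrodes.labels, reference="raw")
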
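"""Classical potential-based three-layer BEM and single-dipole fitting.

This is the inverse engine of the study: the surface potential on nested
SKIN/SKULL/BRAIN interfaces satisfies the piecewise-homogeneous double-layer
(Geselowitz-type) relation

    (sigma- + sigma+)/2 phi(r) =
        sigma_src phi_inf(r)
        + 1/(4 pi) sum_j (sigma_j- - sigma_j+) int_{S_j} phi(r') dOmega_r(r')

with dOmega the solid-angle element seen from r.  It is discretized by
centroid collocation with per-facet constant potentials and exact van
Oosterom-Strackee solid angles; the rank deficiency of the insulated
(outer conductivity zero) problem is removed by Lynn-Timlake deflation.
Potentials are therefore determined up to a constant and all comparisons are
average-referenced.

For dipole fitting, the LU factorization yields an electrode transfer matrix
(electrode voltages = T . source-term vector), making leadfields cheap; the
residual-variance objective

    RV(p) = ||V - L(p) q_hat(p)||^2 / ||V||^2,   q_hat = argmin_q ||V - L q||

is minimized over position p by a derivative-free simplex search, optionally
preceded by a grid scan over source positions inside the innermost surface.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg
import scipy.optimize

from . import _kernels
from .geometry import ElectrodeArray, LayeredHeadModel
from .sources import CurrentDipole

__all__ = ["PotentialBemModel", "LeadfieldMatrix", "FitResult",
           "assemble_potential_bem", "leadfield", "fit_dipole",
           "residual_variance", "solid_angles"]


def solid_angles(triangles: np.ndarray, points: np.ndarray,
                 skip_diagonal: bool = False) -> np.ndarray:
    """Signed solid angles (van Oosterom-Strackee) of each triangle seen from
    each point; positive when an outward-oriented surface encloses the point."""
    return _kernels.solid_angle_matrix(
        np.ascontiguousarray(triangles, dtype=float),
        np.ascontiguousarray(np.atleast_2d(points), dtype=float),
        skip_diagonal)


@dataclasses.dataclass
class LeadfieldMatrix:
    """Electrodes x 3 gain matrix at a candidate position (V per A m),
    average-referenced."""

    position: np.ndarray
    gain: np.ndarray


@dataclasses.dataclass
class FitResult:
    """Fitted dipole with residual variance and search metadata."""

    position: np.ndarray
    orientation: np.ndarray
    moment: float
    rv: float
    n_eval: int
    strategy: str

    @property
    def moment_vector(self) -> np.ndarray:
        return self.moment * self.orientation


class PotentialBemModel:
    """Assembled potential-based BEM with an electrode transfer matrix.

    Build with :func:`assemble_potential_bem`; attach electrodes with
    :meth:`set_electrodes` before computing leadfields or fitting.
    """

    def __init__(self, model: LayeredHeadModel, outer_conductivity: float = 0.0):
        self.head = model
        self.outer_conductivity = float(outer_conductivity)
        surfaces = model.surfaces
        self.triangles = np.concatenate([s.triangles for s in surfaces])
        self.centers = np.concatenate([s.centers for s in surfaces])
        self.surface_id = np.concatenate([
            np.full(s.n_faces, i, dtype=np.int64) for i, s in enumerate(surfaces)])
        sig_in = model.conductivities
        sig_out = np.concatenate([[self.outer_conductivity],
                                  model.conductivities[:-1]])
        self.sigma_mean = 0.5 * (sig_in + sig_out)[self.surface_id]
        self.sigma_jump = (sig_in - sig_out)[self.surface_id]
        self.sigma_src = model.source_conductivity
        self.n_nodes = len(self.centers)
        self._lu = None
        self.deflated = False
        self.electrodes = None
        self._transfer = None
        self._grid_cache = {}
        # innermost-surface containment for grid/fit domain checks
        inner = surfaces[-1]
        self._inner_radius = None
        center = inner.vertices.mean(axis=0)
        rad = np.linalg.norm(inner.vertices - center, axis=1)
        if np.ptp(rad) < 1e-6 * rad.mean():  # concentric sphere fast path
            self._inner_center = center
            self._inner_radius = rad.min()
        else:
            self._inner_mesh = inner

    # -- assembly -----------------------------------------------------------

    def _assemble(self):
        omega = solid_angles(self.triangles, self.centers, skip_diagonal=True)
        # A = diag(sigma_mean) - Omega * diag(sigma_jump)/(4 pi); constants
        # are in the nullspace when the exterior is insulating
        omega *= -self.sigma_jump / (4 * np.pi)
        omega[np.diag_indices(self.n_nodes)] += self.sigma_mean
        if self.outer_conductivity == 0.0:
            omega += self.sigma_mean.mean() / self.n_nodes
            self.deflated = True
        self._lu = scipy.linalg.lu_factor(omega, overwrite_a=True,
                                          check_finite=False)

    @property
    def lu(self):
        if self._lu is None:
            self._assemble()
        return self._lu

    def source_vector(self, position, moment_vector) -> np.ndarray:
        """Right-hand side sigma_src * phi_inf at the collocation nodes; the
        source-compartment conductivity cancels against phi_inf's 1/sigma."""
        delta = self.centers - np.asarray(position)
        r3 = np.linalg.norm(delta, axis=1) ** 3
        return delta @ np.asarray(moment_vector) / (4 * np.pi * r3)

    def solve(self, dipole: CurrentDipole) -> np.ndarray:
        """Interface potentials (determined up to a constant when deflated)."""
        b = self.source_vector(dipole.position, dipole.moment_vector)
        return scipy.linalg.lu_solve(self.lu, b, check_finite=False)

    # -- electrodes and transfer matrix -------------------------------------

    def set_electrodes(self, electrodes: ElectrodeArray):
        """Attach a skin electrode montage and build the 256 x M transfer
        matrix T = S A^-1 via one multi-RHS transposed solve."""
        skin_faces = int((self.surface_id == 0).sum())
        if np.any(electrodes.facet_index >= skin_faces):
            raise IndexError("electrode facet index out of range for the skin surface")
        self.electrodes = electrodes
        sel = np.zeros((self.n_nodes, electrodes.n))
        sel[electrodes.facet_index, np.arange(electrodes.n)] = 1.0
        self._transfer = scipy.linalg.lu_solve(self.lu, sel, trans=1,
                                               check_finite=False).T

    def electrode_potentials(self, position, moment_vector) -> np.ndarray:
        """Average-referenced electrode voltages for a dipole."""
        if self._transfer is None:
            raise RuntimeError("call set_electrodes first")
        v = self._transfer @ self.source_vector(position, moment_vector)
        return v - v.mean()

    def contains(self, points) -> np.ndarray:
        """Inside test against the innermost (BRAIN) surface."""
        points = np.atleast_2d(points)
        if self._inner_radius is not None:
            return (np.linalg.norm(points - self._inner_center, axis=1)
                    < self._inner_radius)
        return self._inner_mesh.contains(points)

    # -- source grid ---------------------------------------------------------

    def source_grid(self, resolution: float = 0.005) -> np.ndarray:
        """Regular grid of candidate positions inside the innermost surface."""
        key = round(float(resolution), 9)
        if key not in self._grid_cache:
            verts = self.head.surfaces[-1].vertices
            lo, hi = verts.min(axis=0), verts.max(axis=0)
            axes = [np.arange(lo[k], hi[k] + resolution / 2, resolution)
                    for k in range(3)]
            nodes = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
            nodes = nodes[self.contains(nodes)]
            if len(nodes) == 0:
                raise ValueError("no grid nodes inside the innermost surface")
            self._grid_cache[key] = (nodes, None)
        return self._grid_cache[key][0]

    def grid_leadfields(self, resolution: float = 0.005) -> np.ndarray:
        """(n_nodes, n_electrodes, 3) average-referenced leadfields for the
        whole source grid, computed once and cached."""
        key = round(float(resolution), 9)
        nodes = self.source_grid(resolution)
        if self._grid_cache[key][1] is None:
            lf = np.empty((len(nodes), self.electrodes.n, 3))
            chunk = max(1, 2_000_000 // self.n_nodes)
            for start in range(0, len(nodes), chunk):
                pos = np.ascontiguousarray(nodes[start:start + chunk])
                g = _kernels.dipole_rhs_kernel(self.centers, pos)
                block = self._transfer @ g  # (n_el, 3*chunk)
                block = block.reshape(self.electrodes.n, len(pos), 3)
                lf[start:start + len(pos)] = np.moveaxis(block, 0, 1)
            lf -= lf.mean(axis=1, keepdims=True)
            self._grid_cache[key] = (nodes, lf)
        return self._grid_cache[key][1]


def assemble_potential_bem(model: LayeredHeadModel,
                           outer_conductivity: float = 0.0) -> PotentialBemModel:
    """Assemble (and factorize lazily) the potential-based BEM system for a
    nested layered model (three layers in the study's inverse setting)."""
    bem = PotentialBemModel(model, outer_conductivity=outer_conductivity)
    return bem


def leadfield(model: PotentialBemModel, position) -> LeadfieldMatrix:
    """Electrodes x 3 gain at ``position`` (columns: unit moments along
    x, y, z), average-referenced."""
    position = np.asarray(position, dtype=float)
    if not model.contains(position)[0]:
        raise ValueError("leadfield position must lie inside the BRAIN surface")
    gain = np.column_stack([
        model.electrode_potentials(position, e) for e in np.eye(3)])
    return LeadfieldMatrix(position, gain)


def residual_variance(v: np.ndarray, v_fit: np.ndarray) -> float:
    """Fraction of data variance unexplained by the fit:
    RV = ||V - V_fit||^2 / ||V||^2."""
    v = np.asarray(v, dtype=float)
    v_fit = np.asarray(v_fit, dtype=float)
    if v.shape != v_fit.shape:
        raise ValueError("voltage vectors must have equal length")
    denom = float(v @ v)
    if denom == 0.0:
        raise ZeroDivisionError("residual variance undefined for zero data")
    diff = v - v_fit
    return float(diff @ diff) / denom


def _rv_at(model: PotentialBemModel, position, v_data):
    """(rv, q_hat) at a candidate position via least-squares moment fit."""
    gain = np.column_stack([
        model.electrode_potentials(position, e) for e in np.eye(3)])
    q, *_ = np.linalg.lstsq(gain, v_data, rcond=None)
    return residual_variance(v_data, gain @ q), q


def _grid_scan(model: PotentialBemModel, v_data, resolution):
    nodes = model.source_grid(resolution)
    lf = model.grid_leadfields(resolution)
    # batched 3x3 normal equations
    ata = np.einsum("nij,nik->njk", lf, lf)
    atv = np.einsum("nij,i->nj", lf, v_data)
    q = np.linalg.solve(ata, atv[..., None])[..., 0]
    vfit = np.einsum("nij,nj->ni", lf, q)
    rv = np.einsum("ni,ni->n", v_data[None, :] - vfit, v_data[None, :] - vfit)
    rv = rv / (v_data @ v_data)
    best = int(np.argmin(rv))
    return nodes[best], float(rv[best])


def fit_dipole(data, model: PotentialBemModel, strategy: str = "both",
               grid_resolution: float = 0.005, start=None,
               xatol: float = 1e-5, maxfev: int = 400) -> FitResult:
    """Single-dipole fit (free position and orientation) minimizing residual
    variance.

    ``strategy``: ``"start"`` runs a simplex search from ``start``;
    ``"grid"`` scans the source grid and refines from the best node;
    ``"both"`` runs the two and returns the lower-RV result.
    ``data`` is an EEGSample or voltage array (channel count must match the
    model's electrodes); fitting uses average-referenced voltages.
    """
    if model.electrodes is None:
        raise RuntimeError("model has no electrodes; call set_electrodes")
    v = np.asarray(getattr(data, "voltages", data), dtype=float)
    if v.shape != (model.electrodes.n,):
        raise ValueError("data channel count does not match the electrode array")
    v = v - v.mean()
    if strategy not in ("start", "grid", "both"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if strategy in ("start", "both") and start is None:
        raise ValueError("strategy requiring a start point needs `start`")

    candidates = []
    if strategy in ("grid", "both"):
        node, _ = _grid_scan(model, v, grid_resolution)
        candidates.append(("grid", node))
    if strategy in ("start", "both"):
        candidates.append(("start", np.asarray(start, dtype=float)))

    best = None
    for label, p0 in candidates:
        n_eval = [0]

        def objective(p):
            n_eval[0] += 1
            inside = model.contains(p)[0]
            if not inside:
                # push the simplex back toward the source region
                dist = np.linalg.norm(p - model.head.surfaces[-1].vertices.mean(axis=0))
                return 1.0 + dist
            return _rv_at(model, p, v)[0]

        res = scipy.optimize.minimize(
            objective, p0, method="Nelder-Mead",
            options={"xatol": xatol, "fatol": 1e-14, "maxfev": maxfev})
        p_fit = res.x
        if not model.contains(p_fit)[0]:
            p_fit = p0
        rv, q = _rv_at(model, p_fit, v)
        moment = float(np.linalg.norm(q))
        orient = q / moment if moment > 0 else np.array([0.0, 0.0, 1.0])
        fit = FitResult(p_fit, orient, moment, rv, n_eval[0], label)
        if best is None or fit.rv < best.rv:
            best = fit
    return best
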
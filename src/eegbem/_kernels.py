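"""Numba hot loops for the O(M^2) boundary-element sums.

All kernels work on flat facet arrays (centers, outward normals, areas).
The charge-equation kernels use the diagonally scaled form of the collocation
system (multiply through by 2*eps0 so the diagonal is 1); callers restore
physical units.
"""

import numpy as np
from numba import njit, prange

INV_2PI = 1.0 / (2.0 * np.pi)


@njit(parallel=True, fastmath=True, cache=True)
def charge_matvec(centers, normals, areas, contrast, rho):
    """Scaled charge operator: out_m = rho_m - (K_m/2pi) * sum_{n!=m}
    rho_n A_n n_m.(r_m - r_n)/|r_m - r_n|^3."""
    m_tot = centers.shape[0]
    out = np.empty(m_tot)
    for m in prange(m_tot):
        cx = centers[m, 0]
        cy = centers[m, 1]
        cz = centers[m, 2]
        nx = normals[m, 0]
        ny = normals[m, 1]
        nz = normals[m, 2]
        acc = 0.0
        for n in range(m_tot):
            if n == m:
                continue
            dx = cx - centers[n, 0]
            dy = cy - centers[n, 1]
            dz = cz - centers[n, 2]
            r2 = dx * dx + dy * dy + dz * dz
            inv_r3 = 1.0 / (r2 * np.sqrt(r2))
            acc += rho[n] * areas[n] * (nx * dx + ny * dy + nz * dz) * inv_r3
        out[m] = rho[m] - contrast[m] * INV_2PI * acc
    return out


@njit(parallel=True, fastmath=True, cache=True)
def charge_rows_into(centers, normals, areas, contrast, row_idx, mat):
    """Write rows ``row_idx`` of the dense scaled charge operator into the
    (possibly capacity-strided) matrix view ``mat``.  Branch-free inner loop
    (the self entry is masked) so the compiler can vectorize it."""
    m_tot = centers.shape[0]
    for i in prange(len(row_idx)):
        m = row_idx[i]
        cx = centers[m, 0]
        cy = centers[m, 1]
        cz = centers[m, 2]
        nx = normals[m, 0]
        ny = normals[m, 1]
        nz = normals[m, 2]
        coef = -contrast[m] * INV_2PI
        for n in range(m_tot):
            dx = cx - centers[n, 0]
            dy = cy - centers[n, 1]
            dz = cz - centers[n, 2]
            r2 = dx * dx + dy * dy + dz * dz
            # the n == m numerator is exactly zero, so a tiny denominator
            # guard keeps the loop branchless without affecting any entry
            inv_r3 = 1.0 / np.sqrt(r2 * r2 * r2 + 1e-300)
            mat[m, n] = coef * areas[n] * (nx * dx + ny * dy + nz * dz) * inv_r3
        mat[m, m] = 1.0


@njit(parallel=True, fastmath=True, cache=True)
def charge_cols_into(centers, normals, areas, contrast, col_idx, mat):
    """Write columns ``col_idx`` of the dense scaled charge operator into
    ``mat``."""
    m_tot = centers.shape[0]
    k = len(col_idx)
    for m in prange(m_tot):
        cx = centers[m, 0]
        cy = centers[m, 1]
        cz = centers[m, 2]
        nx = normals[m, 0]
        ny = normals[m, 1]
        nz = normals[m, 2]
        coef = -contrast[m] * INV_2PI
        for j in range(k):
            n = col_idx[j]
            if n == m:
                mat[m, m] = 1.0
                continue
            dx = cx - centers[n, 0]
            dy = cy - centers[n, 1]
            dz = cz - centers[n, 2]
            r2 = dx * dx + dy * dy + dz * dz
            inv_r3 = 1.0 / (r2 * np.sqrt(r2))
            mat[m, n] = coef * areas[n] * (nx * dx + ny * dy + nz * dz) * inv_r3


def _subpanel_barycentric(levels: int) -> np.ndarray:
    """Barycentric coordinates of the centroids of the 4**levels congruent
    subtriangles from recursive midpoint subdivision (rows sum to 1)."""
    tris = [np.eye(3)]
    for _ in range(levels):
        nxt = []
        for t in tris:
            v0, v1, v2 = t
            m01, m12, m20 = (v0 + v1) / 2, (v1 + v2) / 2, (v2 + v0) / 2
            nxt += [np.array([v0, m01, m20]), np.array([v1, m12, m01]),
                    np.array([v2, m20, m12]), np.array([m01, m12, m20])]
        tris = nxt
    return np.array([t.mean(axis=0) for t in tris])


# 64-point midpoint rule on congruent subtriangles: near-singular panel
# integrals are evaluated with this instead of the single-centroid kernel
QUAD_BARY = _subpanel_barycentric(3)


@njit(parallel=True, fastmath=True, cache=True)
def near_field_entries(triangles, centers, normals, areas, contrast,
                       rows, cols, bary):
    """Scaled operator entries for near pairs using subdivided-panel
    quadrature of the exact single-layer field integral:

        entry(m, n) = -(K_m / 2 pi) * n_m . int_panel_n (r_m - r')
                                              / |r_m - r'|^3 ds'
    """
    n_pairs = len(rows)
    n_quad = bary.shape[0]
    out = np.empty(n_pairs)
    for p in prange(n_pairs):
        m = rows[p]
        n = cols[p]
        cx = centers[m, 0]
        cy = centers[m, 1]
        cz = centers[m, 2]
        acc = 0.0
        for q in range(n_quad):
            qx = (bary[q, 0] * triangles[n, 0, 0]
                  + bary[q, 1] * triangles[n, 1, 0]
                  + bary[q, 2] * triangles[n, 2, 0])
            qy = (bary[q, 0] * triangles[n, 0, 1]
                  + bary[q, 1] * triangles[n, 1, 1]
                  + bary[q, 2] * triangles[n, 2, 1])
            qz = (bary[q, 0] * triangles[n, 0, 2]
                  + bary[q, 1] * triangles[n, 1, 2]
                  + bary[q, 2] * triangles[n, 2, 2])
            dx = cx - qx
            dy = cy - qy
            dz = cz - qz
            r2 = dx * dx + dy * dy + dz * dz
            inv_r3 = 1.0 / (r2 * np.sqrt(r2))
            acc += (normals[m, 0] * dx + normals[m, 1] * dy
                    + normals[m, 2] * dz) * inv_r3
        out[p] = -contrast[m] * INV_2PI * acc * areas[n] / n_quad
    return out


@njit(cache=True)
def repack_rows(buf, m_old, m_new):
    """Widen the row pitch of the matrix stored in the flat buffer prefix
    from m_old to m_new (back to front; row contents keep m_old columns)."""
    for i in range(m_old - 1, 0, -1):
        src = i * m_old
        dst = i * m_new
        for j in range(m_old - 1, -1, -1):
            buf[dst + j] = buf[src + j]


def charge_matrix(centers, normals, areas, contrast):
    """Dense scaled charge operator (unit diagonal)."""
    m_tot = centers.shape[0]
    out = np.empty((m_tot, m_tot))
    charge_rows_into(centers, normals, areas, contrast,
                     np.arange(m_tot, dtype=np.int64), out)
    return out


@njit(parallel=True, fastmath=True, cache=True)
def single_layer_sum(centers, areas, rho, points, self_index):
    """sum_{n != self} rho_n A_n / |p - r_n| at each evaluation point.

    self_index[i] is the facet index to skip for point i (its analytic
    self-integral is added by the caller), or -1 for off-surface points.
    """
    n_pts = points.shape[0]
    m_tot = centers.shape[0]
    out = np.empty(n_pts)
    for i in prange(n_pts):
        px = points[i, 0]
        py = points[i, 1]
        pz = points[i, 2]
        skip = self_index[i]
        acc = 0.0
        for n in range(m_tot):
            if n == skip:
                continue
            dx = px - centers[n, 0]
            dy = py - centers[n, 1]
            dz = pz - centers[n, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            acc += rho[n] * areas[n] / r
        out[i] = acc
    return out


@njit(parallel=True, fastmath=True, cache=True)
def solid_angle_matrix(triangles, points, skip_diagonal):
    """Signed solid angles of triangles seen from points (van Oosterom-
    Strackee).  Positive for an outward-oriented facet of a surface
    enclosing the point.  With skip_diagonal, entry (i, i) is the
    principal-value self term, zero for a planar facet."""
    n_pts = points.shape[0]
    n_tri = triangles.shape[0]
    omega = np.empty((n_pts, n_tri))
    for i in prange(n_pts):
        px = points[i, 0]
        py = points[i, 1]
        pz = points[i, 2]
        for j in range(n_tri):
            if skip_diagonal and i == j:
                omega[i, j] = 0.0
                continue
            ax = triangles[j, 0, 0] - px
            ay = triangles[j, 0, 1] - py
            az = triangles[j, 0, 2] - pz
            bx = triangles[j, 1, 0] - px
            by = triangles[j, 1, 1] - py
            bz = triangles[j, 1, 2] - pz
            cx = triangles[j, 2, 0] - px
            cy = triangles[j, 2, 1] - py
            cz = triangles[j, 2, 2] - pz
            la = np.sqrt(ax * ax + ay * ay + az * az)
            lb = np.sqrt(bx * bx + by * by + bz * bz)
            lc = np.sqrt(cx * cx + cy * cy + cz * cz)
            det = (ax * (by * cz - bz * cy)
                   - ay * (bx * cz - bz * cx)
                   + az * (bx * cy - by * cx))
            denom = (la * lb * lc
                     + (ax * bx + ay * by + az * bz) * lc
                     + (ax * cx + ay * cy + az * cz) * lb
                     + (bx * cx + by * cy + bz * cz) * la)
            omega[i, j] = 2.0 * np.arctan2(det, denom)
    return omega


@njit(parallel=True, fastmath=True, cache=True)
def dipole_rhs_kernel(centers, positions):
    """Infinite-medium dipole kernel (r_m - p)/(4 pi |r_m - p|^3) for a batch
    of source positions; output shape (M, 3 * n_pos), columns grouped by
    position (x, y, z moment components)."""
    m_tot = centers.shape[0]
    n_pos = positions.shape[0]
    out = np.empty((m_tot, 3 * n_pos))
    inv_4pi = 1.0 / (4.0 * np.pi)
    for m in prange(m_tot):
        cx = centers[m, 0]
        cy = centers[m, 1]
        cz = centers[m, 2]
        for p in range(n_pos):
            dx = cx - positions[p, 0]
            dy = cy - positions[p, 1]
            dz = cz - positions[p, 2]
            r2 = dx * dx + dy * dy + dz * dz
            w = inv_4pi / (r2 * np.sqrt(r2))
            out[m, 3 * p] = dx * w
            out[m, 3 * p + 1] = dy * w
            out[m, 3 * p + 2] = dz * w
    return out
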
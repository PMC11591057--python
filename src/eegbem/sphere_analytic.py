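"""Closed-form EEG forward solution for concentric-sphere head models.

For a point current dipole at radius b in the core or any interior shell of
a stack of concentric spherical shells, the potential is expanded in
Legendre series.  In a frame with the dipole on the +z axis and its
tangential moment component along +x,

    phi(r, theta, phi_az) = 1/(4 pi sigma_src) * sum_l
        [ F0_l(r) q_r P_l(cos theta) + F1_l(r) q_t P_l^1(cos theta) cos phi_az ]

where the radial factors follow from continuity of potential and radial
current at every interface and zero radial current into the air outside,
with the known dipole expansion carried by the source shell (different
radial profiles above and below the source radius and between the two
azimuthal orders).  P_l^1 here is sin(theta) dP_l/d(cos theta) (no
Condon-Shortley sign).  Each shell's radial solution is parametrized with
radius ratios <= 1 so the per-degree linear systems stay well conditioned
up to high truncation order.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["SphereModel", "sphere_potential"]


@dataclasses.dataclass
class SphereModel:
    """Concentric shells: descending radii (m), conductivity per shell
    (outermost first, S/m), Legendre truncation order."""

    radii: np.ndarray
    conductivities: np.ndarray
    n_terms: int = 60

    def __post_init__(self):
        self.radii = np.asarray(self.radii, dtype=float)
        self.conductivities = np.asarray(self.conductivities, dtype=float)
        if np.any(np.diff(self.radii) >= 0) or np.any(self.radii <= 0):
            raise ValueError("radii must be positive and strictly decreasing")
        if len(self.radii) != len(self.conductivities):
            raise ValueError("one conductivity per shell required")
        if np.any(self.conductivities <= 0):
            raise ValueError("conductivities must be positive")
        if self.n_terms < 20:
            raise ValueError("n_terms must be at least 20")

    @classmethod
    def from_head_model(cls, model, n_terms: int = 60) -> "SphereModel":
        """Build from a concentric LayeredHeadModel (radii taken as the mean
        vertex radius of each icosphere surface's circumscribed sphere)."""
        radii = [np.linalg.norm(s.vertices, axis=1).max() for s in model.surfaces]
        return cls(np.asarray(radii), model.conductivities, n_terms=n_terms)


def _source_region(radii, b: float) -> int:
    """1-based region index of the source radius (region j spans
    [R_{j+1}, R_j]; region N is the core)."""
    n = len(radii)
    if b >= radii[0]:
        raise ValueError("dipole must lie strictly inside the outer sphere")
    if np.any(np.abs(radii - b) < 1e-12 * radii[0]):
        raise ValueError("dipole may not lie exactly on an interface")
    for j in range(1, n):
        if b > radii[j]:
            return j
    return n


def _radial_factors(model: SphereModel, b: float):
    """Outermost-region radial coefficients for l = 1..L, for the m = 0
    (radial-moment) and m = 1 (tangential-moment) expansions.

    Region j (1-based, outermost first) spans [R_{j+1}, R_j]; its potential is
    a_j (r/R_j)^l + b_j (R_{j+1}/r)^{l+1}.  The source region additionally
    carries the known dipole expansion, which differs above and below the
    source radius b and between the two azimuthal orders:

        m = 0:  r > b:  l q_r b^(l-1) / r^(l+1)
                r < b: -(l+1) q_r r^l / b^(l+2)
        m = 1:  r > b:  q_t b^(l-1) / r^(l+1)
                r < b:  q_t r^l / b^(l+2)

    Returns (a1, b1) with shape (2, L): row 0 for m = 0, row 1 for m = 1.
    (For a single-shell model b1 holds the r^-(l+1) source coefficient.)
    """
    radii = model.radii
    sig = model.conductivities
    n = len(radii)
    j0 = _source_region(radii, b)
    a_out = np.empty((2, model.n_terms))
    b_out = np.empty((2, model.n_terms))
    for i, l in enumerate(range(1, model.n_terms + 1)):
        for m in (0, 1):
            out_coef = float(l) if m == 0 else 1.0
            in_coef = -float(l + 1) if m == 0 else 1.0

            def s_out(r):
                return out_coef * b**(l - 1) / r**(l + 1)

            def ds_out(r):
                return -(l + 1) * out_coef * b**(l - 1) / r**(l + 2)

            def s_in(r):
                return in_coef * (r / b)**l / (b * b)

            def ds_in(r):
                return l * in_coef * (r / b)**l / (b * b * r)

            if n == 1:
                # insulated outer boundary only; source region is the core
                a_out[m, i] = -ds_out(radii[0]) * radii[0] / l
                b_out[m, i] = out_coef * b**(l - 1)
                continue

            size = 2 * n - 1
            A = np.zeros((size, size))
            rhs = np.zeros(size)
            # unknown layout: [a_1, b_1, ..., a_{N-1}, b_{N-1}, a_N]
            row = 0
            # outer boundary (region 1): d phi/dr = 0 at R_1
            A[row, 0] = l / radii[0]
            A[row, 1] = -(l + 1) * (radii[1] / radii[0])**(l + 1) / radii[0]
            if j0 == 1:
                rhs[row] = -ds_out(radii[0])
            row += 1
            for k in range(1, n):  # interface at radius R_(k+1), 1-based
                R = radii[k]
                # outer side: region k, unknowns at columns 2k-2, 2k-1
                ao, bo = 2 * (k - 1), 2 * (k - 1) + 1
                phi_o = {ao: (R / radii[k - 1])**l, bo: 1.0}
                dphi_o = {ao: l * (R / radii[k - 1])**l / R, bo: -(l + 1) / R}
                if k < n - 1:
                    ai, bi = 2 * k, 2 * k + 1
                    phi_i = {ai: 1.0, bi: (radii[k + 1] / R)**(l + 1)}
                    dphi_i = {ai: l / R,
                              bi: -(l + 1) * (radii[k + 1] / R)**(l + 1) / R}
                else:
                    ai = 2 * k
                    phi_i = {ai: 1.0}
                    dphi_i = {ai: l / R}
                # source contributions at this interface (moved to the rhs):
                # the interface is region j0's lower boundary when k == j0
                # (region j0 evaluated below b) and its upper boundary when
                # k + 1 == j0... regions: outer side is region k, inner side
                # region k+1; source lives in region j0.
                src_phi = src_dphi = 0.0
                if k == j0:          # outer side is the source region, r < b
                    src_phi += s_in(R)
                    src_dphi += sig[k - 1] * ds_in(R)
                if k + 1 == j0:      # inner side is the source region, r > b
                    src_phi -= s_out(R)
                    src_dphi -= sig[k] * ds_out(R)
                # potential continuity: phi_outer - phi_inner = -(src terms)
                for col, val in phi_o.items():
                    A[row, col] += val
                for col, val in phi_i.items():
                    A[row, col] -= val
                rhs[row] = -src_phi
                row += 1
                # radial current continuity
                for col, val in dphi_o.items():
                    A[row, col] += sig[k - 1] * val
                for col, val in dphi_i.items():
                    A[row, col] -= sig[k] * val
                rhs[row] = -src_dphi
                row += 1
            x = np.linalg.solve(A, rhs)
            a_out[m, i] = x[0]
            b_out[m, i] = x[1]
    return a_out, b_out


def _legendre_terms(x: np.ndarray, L: int):
    """P_l(x) and dP_l/dx for l = 1..L (rows), via upward recurrence."""
    p_prev = np.ones_like(x)   # P_0
    p = x.copy()               # P_1
    dp = np.ones_like(x)       # P_1'
    P = np.empty((L, len(x)))
    dP = np.empty((L, len(x)))
    P[0] = p
    dP[0] = dp
    for l in range(2, L + 1):
        p_next = ((2 * l - 1) * x * p - (l - 1) * p_prev) / l
        dp = l * (x * p_next - p) / np.where(x * x == 1.0, 1.0, x * x - 1.0)
        # at |x| = 1, P_l'(x) = l(l+1)/2 * (+-1)^{l+1}
        at_pole = np.abs(x) == 1.0
        if np.any(at_pole):
            dp = np.where(at_pole, x**(l + 1) * l * (l + 1) / 2.0, dp)
        p_prev, p = p, p_next
        P[l - 1] = p
        dP[l - 1] = dp
    return P, dP


def sphere_potential(model: SphereModel, dipole, surface_points) -> np.ndarray:
    """Scalp potential (V) of ``dipole`` at points in the outermost shell.

    The dipole may sit in the core or in any interior shell (not exactly on
    an interface, and not in the outermost shell).  Points are expected at or
    slightly below the outer radius; the radial factors are evaluated at each
    point's actual radius within the outermost region.
    """
    points = np.atleast_2d(np.asarray(surface_points, dtype=float))
    r0 = dipole.position
    b = float(np.linalg.norm(r0))
    j0 = _source_region(model.radii, b)
    if j0 == 1 and len(model.radii) > 1:
        raise ValueError("dipole in the outermost shell is not supported")
    q = dipole.moment_vector
    # dipole-aligned frame
    if b > 1e-12 * model.radii[0]:
        ez = r0 / b
    else:
        ez = np.array([0.0, 0.0, 1.0])
    q_r = q @ ez
    q_tan = q - q_r * ez
    q_t = np.linalg.norm(q_tan)
    if q_t > 0:
        ex = q_tan / q_t
    else:
        tmp = np.array([1.0, 0.0, 0.0])
        if abs(ez @ tmp) > 0.9:
            tmp = np.array([0.0, 1.0, 0.0])
        ex = tmp - (tmp @ ez) * ez
        ex /= np.linalg.norm(ex)

    r = np.linalg.norm(points, axis=1)
    if np.any(r <= b):
        raise ValueError("evaluation points must lie in the outermost shell")
    x = np.clip(points @ ez / r, -1.0, 1.0)
    # sin(theta) cos(phi_az) = (p . ex) / |p|
    sc = points @ ex / r

    a1, b1 = _radial_factors(model, b)
    ell = np.arange(1, model.n_terms + 1)
    # radial factors at each point's actual radius within the outer region
    grow = (r[None, :] / model.radii[0])**ell[:, None]
    if len(model.radii) == 1:
        decay = 1.0 / r[None, :]**(ell[:, None] + 1)
    else:
        decay = (model.radii[1] / r[None, :])**(ell[:, None] + 1)
    F0 = a1[0][:, None] * grow + b1[0][:, None] * decay
    F1 = a1[1][:, None] * grow + b1[1][:, None] * decay
    P, dP = _legendre_terms(x, model.n_terms)
    phi = (q_r * F0 * P + q_t * sc[None, :] * F1 * dP).sum(axis=0)
    return phi / (4 * np.pi * model.conductivities[j0 - 1])
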
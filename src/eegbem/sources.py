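"""Point current dipole sources and their impressed (primary) fields.

A current dipole of moment ``I0 * d`` (A m) embedded in an infinite
homogeneous medium of conductivity sigma produces the impressed potential

    phi_i(r) = moment * d_hat . (r - r0) / (4 pi sigma |r - r0|^3)

and impressed field E_i = -grad phi_i.  In the layered models the medium
conductivity is the grey-matter (or BRAIN) value of the conductivity set.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["CurrentDipole", "impressed_potential", "impressed_efield",
           "monopole_pair_potential"]


@dataclasses.dataclass
class CurrentDipole:
    """Point current dipole: position r0 (m), unit direction, moment (A m)."""

    position: np.ndarray
    direction: np.ndarray
    moment: float = 1e-8

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValueError("dipole direction must be nonzero")
        self.direction = d / norm
        if self.moment <= 0:
            raise ValueError("dipole moment must be positive")

    @property
    def moment_vector(self) -> np.ndarray:
        return self.moment * self.direction

    @classmethod
    def from_moment_vector(cls, position, q) -> "CurrentDipole":
        q = np.asarray(q, dtype=float)
        return cls(position, q, float(np.linalg.norm(q)))


def _displacements(dipole, points):
    points = np.atleast_2d(np.asarray(points, dtype=float))
    delta = points - dipole.position
    r = np.linalg.norm(delta, axis=1)
    if np.any(r == 0):
        raise ZeroDivisionError("field evaluation at the dipole position")
    return delta, r


def impressed_potential(dipole: CurrentDipole, points, sigma_medium: float) -> np.ndarray:
    """Infinite-medium dipole potential (V) at the given points."""
    if sigma_medium <= 0:
        raise ValueError("sigma_medium must be positive")
    delta, r = _displacements(dipole, points)
    return dipole.moment * (delta @ dipole.direction) / (4 * np.pi * sigma_medium * r**3)


def impressed_efield(dipole: CurrentDipole, points, sigma_medium: float) -> np.ndarray:
    """Impressed field E_i = -grad phi_i (V/m), analytic gradient."""
    if sigma_medium <= 0:
        raise ValueError("sigma_medium must be positive")
    delta, r = _displacements(dipole, points)
    proj = delta @ dipole.direction
    coef = dipole.moment / (4 * np.pi * sigma_medium)
    return coef * (3 * proj[:, None] * delta / r[:, None]**5
                   - dipole.direction[None, :] / r[:, None]**3)


def monopole_pair_potential(dipole: CurrentDipole, points, sigma_medium: float,
                            length: float) -> np.ndarray:
    """Finite-length dipole: explicit +-I0 monopoles separated by ``length``
    along the dipole axis (I0 = moment / length)."""
    if length <= 0:
        raise ValueError("length must be positive")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    half = 0.5 * length * dipole.direction
    i0 = dipole.moment / length
    r_pos = np.linalg.norm(points - (dipole.position + half), axis=1)
    r_neg = np.linalg.norm(points - (dipole.position - half), axis=1)
    if np.any(r_pos == 0) or np.any(r_neg == 0):
        raise ZeroDivisionError("evaluation at a monopole position")
    return i0 / (4 * np.pi * sigma_medium) * (1.0 / r_pos - 1.0 / r_neg)
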
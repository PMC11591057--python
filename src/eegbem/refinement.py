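"""Adaptive mesh refinement for the charge-based forward solver.

Conventional AMR ranks facets by the total charge magnitude C_m = |rho_m| A_m
from the previous solve, subdivides the top fraction (default 1%) of eligible
facets into four congruent children, re-solves, and stops once the electrode
voltage vector changes by less than the stop threshold (default 1%) between
steps:  ||V_n - V_{n-1}||_2 / ||V_{n-1}||_2 < stop.  The V_n here are
average-referenced: electrode potentials are only defined up to a reference,
and the single-ended collocation read-out carries a large common-mode level
that would otherwise dominate the change norm and stall the criterion.

b-refinement replaces the solved charge by its zero-order surrogate, the
impressed-field magnitude: C_m = |E_i(r_m)| A_m.  Refinement passes are then
free of intermediate solves and a single full solve finishes the job.

The skin surface is never refined (it is the read-out region of interest).
Children lie in the parent's plane, so refinement changes no geometry; the
per-facet constant basis tolerates the resulting hanging nodes.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np

from .forward import BemSystem, ChargeSolution, electrode_voltages, solve_charges
from .sources import CurrentDipole, impressed_efield

__all__ = ["amr_cost", "b_cost", "refine_top_fraction", "run_amr",
           "run_b_amr", "AmrResult"]


def amr_cost(solution: ChargeSolution, system: BemSystem) -> np.ndarray:
    """Conventional AMR cost: total charge magnitude per facet, |rho_m| A_m."""
    return np.abs(solution.rho) * system.areas


def b_cost(dipole: CurrentDipole, system: BemSystem) -> np.ndarray:
    """Zero-order (incident-field) cost: |E_i(r_m)| A_m."""
    ei = impressed_efield(dipole, system.centers, system.sigma_src)
    return np.linalg.norm(ei, axis=1) * system.areas


def refine_top_fraction(system: BemSystem, costs: np.ndarray,
                        fraction: float = 0.01,
                        exclude_surfaces=(0,)) -> BemSystem:
    """Subdivide the ceil(fraction * M_eligible) highest-cost eligible facets
    into four midpoint children (ties broken by ascending facet index).

    Children inherit the parent's contrast and surface id.  The first child
    takes over the parent's facet slot and the remaining three are appended,
    so facet indices of untouched facets (in particular the whole skin block)
    remain valid.
    """
    new_system, _ = _refine_with_map(system, costs, fraction, exclude_surfaces)
    return new_system


def _refine_with_map(system: BemSystem, costs, fraction, exclude_surfaces):
    """refine_top_fraction returning also the indices of facets whose
    geometry changed (parent slots + appended tail), for incremental
    operator updates."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    costs = np.asarray(costs, dtype=float)
    if costs.shape != (system.n_facets,):
        raise ValueError("one cost per facet required")
    eligible = ~np.isin(system.surface_id, np.atleast_1d(exclude_surfaces))
    n_eligible = int(eligible.sum())
    if n_eligible == 0:
        warnings.warn("all facets excluded from refinement; returning system unchanged")
        return system, np.empty(0, dtype=np.int64)
    n_refine = math.ceil(fraction * n_eligible)
    elig_idx = np.flatnonzero(eligible)
    # stable sort on descending cost -> ties broken by ascending facet index
    order = elig_idx[np.argsort(-costs[elig_idx], kind="stable")]
    parents = np.sort(order[:n_refine])

    m_old = system.n_facets
    children = _subdivide(system.triangles[parents])  # (k, 4, 3, 3)
    tri = np.concatenate([system.triangles, children[:, 1:].reshape(-1, 3, 3)])
    tri[parents] = children[:, 0]
    contrast = np.concatenate([system.contrast,
                               np.repeat(system.contrast[parents], 3)])
    sid = np.concatenate([system.surface_id,
                          np.repeat(system.surface_id[parents], 3)])
    new_system = BemSystem(tri, contrast, sid, n_surfaces=system.n_surfaces,
                           sigma_src=system.sigma_src,
                           skin_surface=system.skin_surface)
    changed = np.concatenate([parents,
                              np.arange(m_old, m_old + 3 * len(parents))])
    return new_system, changed


def _subdivide(tri: np.ndarray) -> np.ndarray:
    """Midpoint subdivision: each (3,3) triangle -> four congruent children
    with the parent's orientation; shape (k, 4, 3, 3)."""
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    m01 = 0.5 * (v0 + v1)
    m12 = 0.5 * (v1 + v2)
    m20 = 0.5 * (v2 + v0)
    return np.stack([
        np.stack([v0, m01, m20], axis=1),
        np.stack([v1, m12, m01], axis=1),
        np.stack([v2, m20, m12], axis=1),
        np.stack([m01, m12, m20], axis=1),
    ], axis=1)


def expand_to_children(values: np.ndarray, parents: np.ndarray) -> np.ndarray:
    """Carry per-facet values over a refinement step (children inherit the
    parent's value); used to warm-start the solver."""
    return np.concatenate([values, np.repeat(values[parents], 3)])


@dataclasses.dataclass
class AmrResult:
    """Converged refinement run: final system/solution plus the per-step
    voltage history and diagnostics."""

    system: BemSystem
    solution: ChargeSolution
    steps: int
    converged: bool
    voltages: list
    rel_changes: list
    log: list

    @property
    def final_voltages(self) -> np.ndarray:
        return self.voltages[-1]


def _plan_capacity(m0: int, n_eligible: int, fraction: float, steps: int) -> int:
    """Exact facet count after ``steps`` refinement rounds (each round
    subdivides ceil(fraction * eligible) facets, each adding 3 facets)."""
    e, added = n_eligible, 0
    for _ in range(steps):
        r = math.ceil(fraction * e)
        e += 3 * r
        added += 3 * r
    return m0 + added


def amr_capacity(system: BemSystem, fraction: float = 0.01,
                 max_steps: int = 12, exclude_surfaces=(0,)) -> int:
    """Facet capacity needed by a full-length AMR run (for sizing a reusable
    dense-operator workspace)."""
    eligible = int((~np.isin(system.surface_id,
                             np.atleast_1d(exclude_surfaces))).sum())
    return _plan_capacity(system.n_facets, eligible, fraction, max_steps)


def run_amr(system: BemSystem, dipole: CurrentDipole, electrodes,
            stop: float = 0.01, fraction: float = 0.01, max_steps: int = 12,
            tol: float = 1e-5, exclude_surfaces=(0,),
            dense_limit: int = None, base_operator=None,
            workspace=None) -> AmrResult:
    """Conventional AMR loop: solve -> cost -> refine until the relative
    electrode-voltage change drops below ``stop`` or ``max_steps`` is hit.

    When the projected final facet count fits a dense operator in memory, the
    operator matrix is updated incrementally across refinement steps and each
    GMRES solve is warm-started from the previous charge density (children
    inherit their parent's value); otherwise each step solves from scratch.
    """
    if stop <= 0:
        raise ValueError("stop must be positive")
    from .forward import DENSE_LIMIT, DenseOperator
    if dense_limit is None:
        dense_limit = DENSE_LIMIT
    eligible = int((~np.isin(system.surface_id, np.atleast_1d(exclude_surfaces))).sum())
    capacity = _plan_capacity(system.n_facets, eligible, fraction, max_steps)
    if capacity > dense_limit:
        op = None
    elif workspace is not None:
        # reuse a persistent working buffer across per-dipole runs
        if workspace.system is not system or workspace.n_facets != system.n_facets:
            workspace.reassemble(system)
        op = workspace
    elif base_operator is not None and base_operator.system is system:
        op = base_operator.clone(capacity)
    else:
        op = DenseOperator(system, capacity=capacity)

    solution = op.solve(dipole, tol=tol) if op else solve_charges(system, dipole, tol=tol)
    v_prev = electrode_voltages(system, solution, dipole, electrodes).voltages
    voltages = [v_prev]
    rel_changes = []
    log = [_log_row(0, system, solution, np.nan)]
    converged = False
    steps = 0
    for step in range(1, max_steps + 1):
        costs = amr_cost(solution, system)
        system, changed = _refine_with_map(system, costs, fraction, exclude_surfaces)
        if len(changed) == 0:
            break
        parents = changed[:len(changed) // 4]
        x0 = expand_to_children(solution.rho, parents)
        if op is not None:
            op.update(system, changed)
            solution = op.solve(dipole, tol=tol, x0=x0)
        else:
            solution = solve_charges(system, dipole, tol=tol)
        v = electrode_voltages(system, solution, dipole, electrodes).voltages
        ref_v = v - v.mean()
        ref_prev = v_prev - v_prev.mean()
        rel = float(np.linalg.norm(ref_v - ref_prev) / np.linalg.norm(ref_prev))
        voltages.append(v)
        rel_changes.append(rel)
        log.append(_log_row(step, system, solution, rel))
        steps = step
        v_prev = v
        if rel < stop:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"AMR did not meet the {stop:.2%} voltage-change criterion within "
            f"{max_steps} steps"
            + (f" (last change {rel_changes[-1]:.3e})" if rel_changes else ""))
    return AmrResult(system, solution, steps, converged, voltages, rel_changes, log)


def run_b_amr(system: BemSystem, dipole: CurrentDipole, passes: int = 6,
              fraction: float = 0.01, tol: float = 1e-5,
              exclude_surfaces=(0,), solver_kwargs=None):
    """b-refinement: ``passes`` incident-field-driven refinement passes with
    no intermediate solves, then one full charge solve.

    Returns (refined system, ChargeSolution).
    """
    if passes < 0:
        raise ValueError("passes must be non-negative")
    solver_kwargs = solver_kwargs or {}
    for _ in range(passes):
        costs = b_cost(dipole, system)
        system = refine_top_fraction(system, costs, fraction=fraction,
                                     exclude_surfaces=exclude_surfaces)
    solution = solve_charges(system, dipole, tol=tol, **solver_kwargs)
    return system, solution


def _log_row(step, system, solution, rel_change):
    return {
        "step": step,
        "n_facets": system.n_facets,
        "rel_voltage_change": rel_change,
        "residual": solution.residual_norm,
        "iterations": solution.iterations,
    }
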
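import numpy as np
import pytest

from eegbem.forward import (EPS0, BemSystem, DenseOperator, apply_operator,
                            electrode_voltages, solve_charges,
                            surface_potential)
from eegbem.geometry import (LayeredHeadModel, make_icosphere,
                             make_layered_sphere_model, place_electrodes)
from eegbem.sources import CurrentDipole, impressed_potential
from eegbem.error_analysis import rdm


def two_facet_system():
    """Hand-set two-facet toy geometry (one facet per 'surface')."""
    tri = np.array([
        [[0.0, 0.0, 0.0], [0.01, 0.0, 0.0], [0.0, 0.01, 0.0]],
        [[0.0, 0.0, 0.05], [0.01, 0.0, 0.05], [0.0, 0.01, 0.05]],
    ])
    return BemSystem(tri, np.array([0.5, -0.8]), np.array([0, 1]),
                     n_surfaces=2, sigma_src=0.33)


class TestOperator:
    def test_zero_charge_maps_to_zero(self):
        system = two_facet_system()
        out = apply_operator(system, np.zeros(2))
        assert np.array_equal(out, np.zeros(2))

    def test_two_facet_system_matches_hand_formula(self):
        system = two_facet_system()
        rho = np.array([3.0e-12, -1.5e-12])
        out = apply_operator(system, rho)
        # independent scalar arithmetic
        area = 0.5 * 0.01 * 0.01
        c0 = np.array([0.01 / 3, 0.01 / 3, 0.0])
        c1 = c0 + [0, 0, 0.05]
        n = np.array([0.0, 0.0, 1.0])
        for m, (cm, K, other) in enumerate([(c0, 0.5, 1), (c1, -0.8, 0)]):
            cn = c1 if other == 1 else c0
            d = cm - cn
            coupling = (rho[other] * area * (n @ d)
                        / (4 * np.pi * EPS0 * np.linalg.norm(d)**3))
            expect = rho[m] / (2 * EPS0) - K * coupling
            assert out[m] == pytest.approx(expect, rel=1e-12)

    def test_wrong_length_rejected(self):
        system = two_facet_system()
        with pytest.raises(ValueError):
            apply_operator(system, np.zeros(3))

    def test_coincident_centers_rejected(self):
        tri = np.array([
            [[0.0, 0.0, 0.0], [0.01, 0.0, 0.0], [0.0, 0.01, 0.0]],
            [[0.0, 0.0, 0.0], [0.01, 0.0, 0.0], [0.0, 0.01, 0.0]],
        ])
        system = BemSystem(tri, np.array([0.5, 0.5]), np.array([0, 1]),
                           n_surfaces=2, sigma_src=0.33)
        with pytest.raises(ValueError):
            apply_operator(system, np.zeros(2))

    def test_dense_matrix_consistent_with_matvec(self, model3_s2):
        # the point-panel (centroid) matrix must reproduce the direct sum
        system = BemSystem.from_model(model3_s2)
        op = DenseOperator(system, near_field=0)
        rng = np.random.default_rng(0)
        rho = rng.normal(size=system.n_facets)
        direct = apply_operator(system, rho)
        assert np.allclose(op.matrix @ rho / (2 * EPS0), direct, rtol=1e-10)


class TestSolve:
    def test_zero_contrast_gives_zero_charge_no_iterations(self):
        model = make_layered_sphere_model(
            [0.09, 0.08], conductivities=[0.3, 0.3], subdivisions=1)
        # kill the skin-air jump as well so every contrast vanishes
        system = BemSystem.from_model(model)
        system.contrast[:] = 0.0
        dip = CurrentDipole([0, 0, 0.02], [1, 0, 0], 1e-8)
        sol = solve_charges(system, dip)
        assert np.array_equal(sol.rho, np.zeros(system.n_facets))
        assert sol.iterations == 0
        pts = np.array([[0.0, 0.0, 0.085]])
        phi = surface_potential(system, sol, dip, pts)
        phi_i = impressed_potential(dip, pts, system.sigma_src)
        assert np.array_equal(phi, phi_i)

    def test_iterative_matches_dense_direct_solve(self, sphere_s2):
        model = LayeredHeadModel([sphere_s2], [0.33])
        system = BemSystem.from_model(model)
        assert system.n_facets <= 500
        dip = CurrentDipole([0, 0, 0.045], [1, 0, 0], 1e-8)
        direct = solve_charges(system, dip, method="direct")
        iterative = solve_charges(system, dip, method="matvec", tol=1e-8)
        scale = np.abs(direct.rho).max()
        assert np.max(np.abs(direct.rho - iterative.rho)) / scale < 1e-6

    def test_charge_neutrality_per_surface(self, system3_s3):
        dip = CurrentDipole([0, 0, 0.05], [1, 0, 0], 1e-8)
        sol = solve_charges(system3_s3, dip)
        for s in range(3):
            mask = system3_s3.surface_id == s
            net = (sol.rho[mask] * system3_s3.areas[mask]).sum()
            total = np.abs(sol.rho[mask] * system3_s3.areas[mask]).sum()
            assert abs(net) / total < 1e-3

    def test_solver_reports_residual_below_tolerance(self, system3_s3):
        dip = CurrentDipole([0.01, 0, 0.05], [0, 1, 0], 1e-8)
        sol = solve_charges(system3_s3, dip, tol=1e-5)
        assert sol.residual_norm <= 1e-5


class TestPotentialsAndVoltages:
    def test_gauge_invariance_of_referenced_comparison(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=32)
        assert rdm(v, v + 0.37) < 1e-12

    def test_electrode_voltages_linear_in_moment(self, homogeneous_model_s3,
                                                 electrodes64):
        system = BemSystem.from_model(homogeneous_model_s3)
        pos, direction = [0, 0, 0.05], [1, 0, 0]
        v1 = electrode_voltages(system, solve_charges(
            system, CurrentDipole(pos, direction, 1e-8)),
            CurrentDipole(pos, direction, 1e-8), electrodes64).voltages
        v2 = electrode_voltages(system, solve_charges(
            system, CurrentDipole(pos, direction, 2e-8)),
            CurrentDipole(pos, direction, 2e-8), electrodes64).voltages
        vflip = electrode_voltages(system, solve_charges(
            system, CurrentDipole(pos, [-1, 0, 0], 1e-8)),
            CurrentDipole(pos, [-1, 0, 0], 1e-8), electrodes64).voltages
        assert np.allclose(v2, 2 * v1, rtol=1e-4)
        assert np.allclose(vflip, -v1, rtol=1e-4)

    def test_same_facet_electrodes_identical(self, homogeneous_model_s3):
        from eegbem.geometry import ElectrodeArray
        system = BemSystem.from_model(homogeneous_model_s3)
        skin = homogeneous_model_s3.surfaces[0]
        arr = ElectrodeArray(skin.centers[[10, 10, 42]],
                             np.array([10, 10, 42]))
        dip = CurrentDipole([0, 0, 0.05], [1, 0, 0], 1e-8)
        sol = solve_charges(system, dip)
        v = electrode_voltages(system, sol, dip, arr).voltages
        assert v[0] == v[1]
        assert v[0] != v[2]

    def test_facet_index_out_of_range(self, homogeneous_model_s3):
        from eegbem.geometry import ElectrodeArray
        system = BemSystem.from_model(homogeneous_model_s3)
        arr = ElectrodeArray(np.zeros((1, 3)), np.array([10**6]))
        dip = CurrentDipole([0, 0, 0.05], [1, 0, 0], 1e-8)
        sol = solve_charges(system, dip)
        with pytest.raises(IndexError):
            electrode_voltages(system, sol, dip, arr)

    def test_self_integral_matches_quadrature(self):
        from eegbem.forward import _centroid_self_integral
        tri = np.array([[[0.0, 0.0, 0.0], [0.02, 0.0, 0.0], [0.003, 0.017, 0.0]]])
        analytic = _centroid_self_integral(tri)[0]
        # barycentric midpoint quadrature refinement
        rng = np.random.default_rng(0)
        w = rng.dirichlet(np.ones(3), size=400000)
        pts = w @ tri[0]
        c = tri[0].mean(axis=0)
        area = 0.5 * np.linalg.norm(np.cross(tri[0, 1] - tri[0, 0],
                                             tri[0, 2] - tri[0, 0]))
        mc = area * np.mean(1.0 / np.linalg.norm(pts - c, axis=1))
        assert analytic == pytest.approx(mc, rel=5e-3)

    def test_homogeneous_sphere_matches_oracle(self, homogeneous_model_s3,
                                               electrodes64):
        from eegbem.sphere_analytic import SphereModel, sphere_potential
        system = BemSystem.from_model(homogeneous_model_s3)
        dip = CurrentDipole([0, 0, 0.05], [1, 0, 0], 1e-8)
        sol = solve_charges(system, dip)
        v = electrode_voltages(system, sol, dip, electrodes64).voltages
        oracle = SphereModel([0.09], [0.33], n_terms=80)
        va = sphere_potential(oracle, dip, electrodes64.positions)
        assert rdm(v, va) < 0.02

    def test_forward_converges_with_uniform_refinement(self, electrodes64):
        """Electrode RDM against the analytic oracle is non-increasing over
        three successive uniform mesh refinement levels."""
        from eegbem.sphere_analytic import SphereModel, sphere_potential
        oracle = SphereModel([0.09], [0.33], n_terms=80)
        dip = CurrentDipole([0, 0, 0.045], [1, 0, 0], 1e-8)
        errors = []
        for sub in (1, 2, 3):
            model = LayeredHeadModel([make_icosphere(0.09, sub)], [0.33])
            system = BemSystem.from_model(model)
            elec = place_electrodes(model.surfaces[0], 64)
            sol = solve_charges(system, dip)
            v = electrode_voltages(system, sol, dip, elec).voltages
            va = sphere_potential(oracle, dip, elec.positions)
            errors.append(rdm(v, va))
        assert errors[0] >= errors[1] >= errors[2]
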
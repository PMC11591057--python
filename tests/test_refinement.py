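import warnings

import numpy as np
import pytest

from eegbem.forward import BemSystem, solve_charges, electrode_voltages
from eegbem.geometry import (LayeredHeadModel, make_icosphere,
                             make_layered_sphere_model, place_electrodes)
from eegbem.refinement import (amr_cost, b_cost, refine_top_fraction, run_amr,
                               run_b_amr, _refine_with_map)
from eegbem.sources import CurrentDipole


@pytest.fixture(scope="module")
def small_system():
    model = make_layered_sphere_model([0.092, 0.086, 0.080],
                                      preset="SimNIBS3", subdivisions=2)
    return BemSystem.from_model(model)


class TestCosts:
    def test_zero_charge_zero_cost(self, small_system):
        from eegbem.forward import ChargeSolution
        sol = ChargeSolution(np.zeros(small_system.n_facets), 0.0, 0)
        assert np.array_equal(amr_cost(sol, small_system),
                              np.zeros(small_system.n_facets))

    def test_cost_linear_in_area(self, small_system):
        from eegbem.forward import ChargeSolution
        rng = np.random.default_rng(0)
        rho = rng.normal(size=small_system.n_facets)
        sol = ChargeSolution(rho, 0.0, 0)
        c1 = amr_cost(sol, small_system)
        doubled = BemSystem(small_system.triangles * 2**0.5,
                            small_system.contrast, small_system.surface_id,
                            small_system.n_surfaces, small_system.sigma_src)
        c2 = amr_cost(sol, doubled)
        assert np.allclose(c2, 2 * c1)

    def test_uniform_charge_cost_orders_by_area(self, small_system):
        from eegbem.forward import ChargeSolution
        sol = ChargeSolution(np.full(small_system.n_facets, 2.0), 0.0, 0)
        costs = amr_cost(sol, small_system)
        assert np.array_equal(np.argsort(costs), np.argsort(small_system.areas))

    def test_b_cost_decays_with_distance(self, small_system):
        dip = CurrentDipole([0, 0, 0.05], [0, 0, 1], 1e-8)
        costs = b_cost(dip, small_system)
        d = np.linalg.norm(small_system.centers - dip.position, axis=1)
        # pure d^-3 falloff on the equal-area innermost surface
        on_brain = small_system.surface_id == 2
        c, dd = costs[on_brain], d[on_brain]
        near = c[dd < np.quantile(dd, 0.2)]
        far = c[dd > np.quantile(dd, 0.8)]
        # cubic distance decay, modulated by the dipole's angular factor
        assert np.median(near) > 5 * np.median(far)
        assert np.argmax(c) in np.argsort(dd)[:len(dd) // 10]

    def test_b_cost_singularity_at_facet_center(self, small_system):
        dip = CurrentDipole(small_system.centers[5], [0, 0, 1], 1e-8)
        with pytest.raises(ZeroDivisionError):
            b_cost(dip, small_system)

    def test_b_cost_ranking_tracks_boundary_charge_ranking(self, small_system):
        """On equal-area sphere caps, the incident-field ranking and the
        zero-order boundary charge |2 eps0 K Ei.n| ranking overlap in the
        top percentile."""
        from eegbem.forward import EPS0
        from eegbem.sources import impressed_efield
        dip = CurrentDipole([0, 0, 0.05], [0, 0, 1], 1e-8)
        costs = b_cost(dip, small_system)
        ei = impressed_efield(dip, small_system.centers, small_system.sigma_src)
        zero_order = (np.abs(2 * EPS0 * small_system.contrast
                             * np.einsum("ij,ij->i", ei, small_system.normals))
                      * small_system.areas)
        k = max(1, small_system.n_facets // 20)
        top_b = set(np.argsort(-costs)[:k].tolist())
        top_q = set(np.argsort(-zero_order)[:k].tolist())
        assert len(top_b & top_q) / k >= 0.5


class TestRefine:
    def test_counting_contract(self):
        # 420 facets with 20-facet skin excluded -> 400 eligible, 1% -> 4
        # parents replaced by 16 children: M' = 420 + 12
        skin = make_icosphere(0.09, 0)          # 20 facets
        inner = make_icosphere(0.05, 2)          # 320 facets
        inner2 = make_icosphere(0.03, 1)         # 80 facets
        model = LayeredHeadModel([skin, inner, inner2], [0.3, 0.2, 0.1])
        system = BemSystem.from_model(model)
        assert system.n_facets == 420
        costs = np.arange(system.n_facets, dtype=float)
        refined = refine_top_fraction(system, costs, fraction=0.01)
        # ceil(0.01 * 400) = 4 parents, each adding 3 facets
        assert refined.n_facets == 432

    def test_children_quarter_area_and_conservation(self, small_system):
        costs = np.random.default_rng(0).random(small_system.n_facets)
        refined, changed = _refine_with_map(small_system, costs, 0.01, (0,))
        parents = changed[:len(changed) // 4]
        assert np.allclose(refined.areas.sum(), small_system.areas.sum(),
                           rtol=1e-12)
        # replaced slot + appended children each carry a quarter of the parent
        for j, p in enumerate(parents):
            parent_area = small_system.areas[p]
            child_ids = [p] + list(changed[len(parents) + 3 * j:
                                           len(parents) + 3 * j + 3])
            assert np.allclose(refined.areas[child_ids], parent_area / 4,
                               rtol=1e-12)

    def test_ties_broken_by_ascending_index(self, small_system):
        costs = np.ones(small_system.n_facets)
        _, changed = _refine_with_map(small_system, costs, 0.01, (0,))
        parents = changed[:len(changed) // 4]
        eligible = np.flatnonzero(small_system.surface_id != 0)
        assert np.array_equal(parents, eligible[:len(parents)])

    def test_skin_never_refined(self, small_system):
        costs = np.zeros(small_system.n_facets)
        costs[small_system.surface_id == 0] = 1e9  # would win on cost
        refined = refine_top_fraction(small_system, costs, fraction=0.01)
        assert (refined.surface_id == 0).sum() == \
            (small_system.surface_id == 0).sum()

    def test_all_excluded_warns_and_noops(self, small_system):
        costs = np.ones(small_system.n_facets)
        with pytest.warns(UserWarning):
            out = refine_top_fraction(small_system, costs,
                                      exclude_surfaces=(0, 1, 2))
        assert out is small_system

    def test_geometry_untouched_volume_invariant(self, small_system):
        costs = np.random.default_rng(1).random(small_system.n_facets)
        refined = refine_top_fraction(small_system, costs, fraction=0.05)
        def volume(system, sid):
            mask = system.surface_id == sid
            return np.einsum("ij,ij->", system.centers[mask],
                             system.normals[mask]
                             * system.areas[mask, None]) / 3.0
        for s in range(3):
            assert volume(refined, s) == pytest.approx(
                volume(small_system, s), rel=1e-12)


class TestAmrLoop:
    def test_identical_voltages_stop_immediately(self, small_system,
                                                 monkeypatch):
        elec = place_electrodes(
            make_layered_sphere_model([0.092, 0.086, 0.080],
                                      preset="SimNIBS3",
                                      subdivisions=2).surfaces[0], 16)
        dip = CurrentDipole([0, 0, 0.04], [1, 0, 0], 1e-8)
        import eegbem.refinement as refinement_mod
        frozen = electrode_voltages(
            small_system, solve_charges(small_system, dip), dip, elec).voltages
        monkeypatch.setattr(
            refinement_mod, "electrode_voltages",
            lambda *a, **k: type("S", (), {"voltages": frozen})())
        res = run_amr(small_system, dip, elec, max_steps=5)
        assert res.converged and res.steps == 1

    def test_nonconforming_mesh_admissible(self, small_system):
        """Hanging nodes from local subdivision do not break the solver."""
        costs = np.random.default_rng(2).random(small_system.n_facets)
        refined = refine_top_fraction(small_system, costs, fraction=0.02)
        dip = CurrentDipole([0, 0, 0.05], [1, 0, 0], 1e-8)
        sol = solve_charges(refined, dip)
        assert sol.residual_norm <= 1e-5

    def test_b_amr_zero_passes_is_base_solve(self, small_system):
        elec_model = make_layered_sphere_model([0.092, 0.086, 0.080],
                                               preset="SimNIBS3",
                                               subdivisions=2)
        dip = CurrentDipole([0, 0, 0.05], [0, 1, 0], 1e-8)
        system_b, sol_b = run_b_amr(small_system, dip, passes=0)
        assert system_b is small_system
        sol_ref = solve_charges(small_system, dip)
        assert np.allclose(sol_b.rho, sol_ref.rho, rtol=1e-10)

    def test_invalid_parameters(self, small_system):
        elec = None
        with pytest.raises(ValueError):
            run_amr(small_system, CurrentDipole([0, 0, 0.04], [1, 0, 0], 1e-8),
                    elec, stop=0.0)
        with pytest.raises(ValueError):
            run_b_amr(small_system,
                      CurrentDipole([0, 0, 0.04], [1, 0, 0], 1e-8), passes=-1)
        with pytest.raises(ValueError):
            refine_top_fraction(small_system,
                                np.ones(small_system.n_facets), fraction=1.5)
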
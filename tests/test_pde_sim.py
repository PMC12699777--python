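"""Reaction-diffusion simulator: scenarios, steady states, ground truth."""

import math
from dataclasses import replace

import numpy as np
import pytest

from flowcomm.ccc_graph import InferenceConfig, build_flow_graph
from flowcomm.pde_sim import (
    KineticParams,
    Scenario,
    extract_ground_truth,
    make_scenario,
    mass_balance_residual,
    scenario_to_inputs,
    simulate_steady_state,
)


def single_site_scenario(p_rate, r_tot, bound=True):
    return Scenario(
        regime="type1",
        cells=["c000"],
        positions={"c000": (0.0, 0.0)},
        ligands=["LG1"],
        receptors=["RC1"],
        connectivity=frozenset({("LG1", "RC1")} if bound else set()),
        production=np.array([[p_rate]]),
        receptor_total=np.array([[r_tot]]),
        seed=0,
    )


class TestMakeScenario:
    def test_type1_with_single_receptor_wires_all_ligands(self):
        sc = make_scenario("type1", n_cells=9, n_ligands=4, n_receptors=1, seed=3)
        assert sc.connectivity == frozenset((lg, "RC1") for lg in sc.ligands)

    def test_same_seed_is_bit_identical(self):
        a = make_scenario("type3", n_cells=16, n_ligands=3, n_receptors=3, seed=11)
        b = make_scenario("type3", n_cells=16, n_ligands=3, n_receptors=3, seed=11)
        assert a.connectivity == b.connectivity
        assert np.array_equal(a.production, b.production)
        assert np.array_equal(a.receptor_total, b.receptor_total)
        assert a.positions == b.positions

    def test_type3_density_constraint_holds_across_seeds(self):
        for seed in range(100):
            sc = make_scenario("type3", n_cells=4, n_ligands=4, n_receptors=3, seed=seed)
            density = len(sc.connectivity) / (4 * 3)
            assert density >= 0.4

    @pytest.mark.parametrize(
        "regime,n_l,n_r",
        [("type1", 2, 3), ("type2", 3, 2), ("type3", 2, 5), ("type3", 5, 2)],
    )
    def test_regime_cardinality_mismatch_rejected(self, regime, n_l, n_r):
        with pytest.raises(ValueError):
            make_scenario(regime, n_cells=9, n_ligands=n_l, n_receptors=n_r)

    def test_non_square_cell_count_rejected(self):
        with pytest.raises(ValueError, match="square"):
            make_scenario("type1", n_cells=10, n_ligands=3, n_receptors=1)

    def test_every_cell_secretes_and_displays_something(self):
        for seed in range(10):
            sc = make_scenario("type1", n_cells=25, n_ligands=5, n_receptors=2, seed=seed)
            assert (sc.production > 0).any(axis=1).all()
            assert (sc.receptor_total > 0).any(axis=1).all()

    def test_lattice_geometry(self):
        p = KineticParams(h=2.0)
        sc = make_scenario("type1", n_cells=9, n_ligands=2, n_receptors=1, params=p)
        xs = sorted({x for x, _ in sc.positions.values()})
        assert xs == [0.0, 2.0, 4.0]


class TestSteadyState:
    def test_zero_production_trivial_steady_state(self):
        sc = single_site_scenario(0.0, 1.5)
        p = KineticParams()
        fields, r_free = simulate_steady_state(sc, p)
        assert fields == {}
        assert np.array_equal(r_free, sc.receptor_total)

    def test_single_site_without_binding_matches_p_over_kdeg(self):
        p = KineticParams(k_deg=0.7)
        sc = single_site_scenario(2.1, 1.0, bound=False)
        fields, _ = simulate_steady_state(sc, p)
        assert fields[("c000", "LG1")][0] == pytest.approx(2.1 / 0.7, rel=1e-10)

    def test_single_site_matches_analytic_quadratic(self):
        # p = k_deg*u + k_on*u*R_free with R_free = R_tot/(1 + K*u), K = k_on/k_off
        p = KineticParams(k_deg=0.4, k_on=2.0, k_off=0.5)
        p_rate, r_tot = 1.3, 0.8
        sc = single_site_scenario(p_rate, r_tot)
        K = p.k_on / p.k_off
        a = p.k_deg * K
        b = p.k_deg + p.k_on * r_tot - p_rate * K
        c = -p_rate
        u_exact = (-b + math.sqrt(b * b - 4 * a * c)) / (2 * a)
        fields, r_free = simulate_steady_state(sc, p)
        u_sim = fields[("c000", "LG1")][0]
        assert abs(u_sim - u_exact) / u_exact < 1e-3
        truth = extract_ground_truth(fields, r_free, sc, p)
        c_exact = K * u_exact * r_tot / (1 + K * u_exact)
        assert truth.amounts[("c000", "c000", "LG1", "RC1")] == pytest.approx(
            c_exact, rel=1e-3
        )

    @pytest.mark.parametrize("regime", ["type1", "type2", "type3"])
    def test_mass_balance_on_default_scenarios(self, regime):
        from flowcomm.bench import REGIME_PANELS

        n_l, n_r = REGIME_PANELS[regime]
        p = KineticParams()
        for seed in (0, 1, 2):
            sc = make_scenario(regime, n_cells=25, n_ligands=n_l, n_receptors=n_r,
                               params=p, seed=seed)
            fields, r_free = simulate_steady_state(sc, p)
            assert mass_balance_residual(fields, r_free, sc, p) < 1e-6

    def test_solver_is_deterministic(self):
        p = KineticParams()
        sc = make_scenario("type1", n_cells=16, n_ligands=4, n_receptors=2, params=p, seed=5)
        f1, r1 = simulate_steady_state(sc, p)
        f2, r2 = simulate_steady_state(sc, p)
        assert np.array_equal(r1, r2)
        for k in f1:
            assert np.array_equal(f1[k], f2[k])

    def test_fields_decay_away_from_the_source(self):
        p = KineticParams()
        sc = make_scenario("type1", n_cells=25, n_ligands=4, n_receptors=1,
                           params=p, seed=2)
        fields, _ = simulate_steady_state(sc, p)
        (src, _), u = next(iter(fields.items()))
        pos = np.array([sc.positions[c] for c in sc.cells])
        src_xy = np.array(sc.positions[src])
        d = np.hypot(*(pos - src_xy).T)
        # concentration at the source exceeds the far corner
        assert u[d.argmin()] > u[d.argmax()]


class TestGroundTruth:
    def test_sources_without_production_contribute_zero(self):
        p = KineticParams()
        sc = make_scenario("type1", n_cells=9, n_ligands=4, n_receptors=2, params=p, seed=1)
        fields, r_free = simulate_steady_state(sc, p)
        truth = extract_ground_truth(fields, r_free, sc, p)
        lig_idx = {lg: a for a, lg in enumerate(sc.ligands)}
        cell_idx = {c: k for k, c in enumerate(sc.cells)}
        for (i, j, lg, rc), v in truth.amounts.items():
            if sc.production[cell_idx[i], lig_idx[lg]] == 0:
                assert v == 0.0

    def test_source_fields_superpose_before_receptor_binding(self):
        p = KineticParams()
        sc = make_scenario("type2", n_cells=9, n_ligands=2, n_receptors=4, params=p, seed=4)
        fields, r_free = simulate_steady_state(sc, p)
        truth = extract_ground_truth(fields, r_free, sc, p)
        K = p.k_on / p.k_off
        rec_idx = {rc: b for b, rc in enumerate(sc.receptors)}
        for (lg, rc) in sc.connectivity:
            u_total = np.zeros(len(sc.cells))
            for (src, l2), u in fields.items():
                if l2 == lg:
                    u_total += u
            for jdx, j in enumerate(sc.cells):
                total = sum(
                    truth.amounts[(i, j, lg, rc)] for i in sc.cells
                )
                assert total == pytest.approx(
                    K * u_total[jdx] * r_free[jdx, rec_idx[rc]], rel=1e-9, abs=1e-12
                )

    def test_nonnegative_and_finite_across_random_scenarios(self):
        p = KineticParams()
        for seed in range(50):
            regime = ["type1", "type2", "type3"][seed % 3]
            n_l, n_r = {"type1": (4, 2), "type2": (2, 4), "type3": (3, 3)}[regime]
            sc = make_scenario(regime, n_cells=9, n_ligands=n_l, n_receptors=n_r,
                               params=p, seed=seed)
            fields, r_free = simulate_steady_state(sc, p)
            truth = extract_ground_truth(fields, r_free, sc, p)
            vals = np.array(list(truth.amounts.values()))
            assert np.all(vals >= 0) and np.all(np.isfinite(vals))

    def test_type1_competition_boosting_one_ligand_starves_the_rest(self):
        p = KineticParams()
        base = make_scenario("type1", n_cells=16, n_ligands=3, n_receptors=1,
                             params=p, seed=7, secretion_prob=1.0, display_prob=1.0)
        boosted = replace(base, production=base.production.copy())
        boosted.production[:, 0] *= 4.0
        truths = []
        for sc in (base, boosted):
            fields, r_free = simulate_steady_state(sc, p)
            truths.append(extract_ground_truth(fields, r_free, sc, p))
        for lg in base.ligands[1:]:
            before = sum(
                v for (i, j, l2, _), v in truths[0].amounts.items() if l2 == lg
            )
            after = sum(
                v for (i, j, l2, _), v in truths[1].amounts.items() if l2 == lg
            )
            assert after < before


class TestScenarioToInputs:
    def test_round_trip_covers_cells_and_genes(self):
        sc = make_scenario("type3", n_cells=9, n_ligands=3, n_receptors=3, seed=0)
        expr, spatial, db = scenario_to_inputs(sc)
        assert expr.cells == sc.cells
        assert expr.genes == sc.ligands + sc.receptors
        assert set(spatial.coords) == set(sc.cells)
        assert {(p.ligand, p.receptor) for p in db.pairs} == set(sc.connectivity)
        assert all(p.prior_confident and p.affinity == 1.0 for p in db.pairs)

    def test_production_maps_to_expression_one_to_one(self):
        sc = make_scenario("type1", n_cells=9, n_ligands=4, n_receptors=2, seed=2)
        expr, _, _ = scenario_to_inputs(sc)
        for k, cell in enumerate(sc.cells):
            for a, lg in enumerate(sc.ligands):
                assert expr.value(cell, lg) == sc.production[k, a]

    def test_flow_graph_respects_lattice_distances(self):
        p = KineticParams()
        sc = make_scenario("type1", n_cells=16, n_ligands=4, n_receptors=2,
                           params=p, seed=0)
        expr, spatial, db = scenario_to_inputs(sc)
        g = build_flow_graph(expr, spatial, db, InferenceConfig(d_cutoff=1.5 * p.h))
        for e in g.edges:
            assert e.distance < 1.5 * p.h
            assert e.source != e.target
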
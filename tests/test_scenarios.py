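import numpy as np
import pytest

import mipflux as mf
from mipflux.constraints import BoundSet
from mipflux.loads import LoadVector
from mipflux.network import derived_fluxes
from mipflux.scenarios import (
    InfeasibleError,
    ObjectiveSpec,
    PrintedScenario,
    calibrate_loads,
    enumerate_scenarios,
    solve_lp,
)

from oracles import box_cut_polytope, enumerate_vertices, polytope_as_system


def toy_box():
    """{0<=x<=1, 0<=y<=1, x+y<=1.5} in engine form."""
    A_ub = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0],
                     [1.0, 1.0]])
    b_ub = np.array([1.0, 0.0, 1.0, 0.0, 1.5])
    return A_ub, b_ub


class TestSolveLP:
    def test_toy_box_maximum(self):
        system, load, bounds, xs = polytope_as_system(*toy_box())
        rec = solve_lp(system, load, bounds, ObjectiveSpec("x0", "maximize"))
        assert rec.optimum == pytest.approx(1.0)

    def test_min_tca_is_the_yield_optimal_scenario(
        self, system, calibration, bounds
    ):
        rec = solve_lp(system, calibration.load, bounds,
                       ObjectiveSpec("r_TCA", "minimize"))
        assert round(rec.yxs, 2) == 0.45
        assert rec.optimum == pytest.approx(0.60, abs=0.01)

    def test_max_pyk_reaches_a_third_of_glucose_uptake(
        self, system, calibration, bounds
    ):
        rec = solve_lp(system, calibration.load, bounds,
                       ObjectiveSpec("r_PYK", "maximize"))
        assert rec.optimum == pytest.approx(0.93, abs=0.01)
        assert rec.optimum / rec.fluxes["r_GLU"] == pytest.approx(1 / 3, abs=0.03)

    def test_infeasible_constraints_are_diagnosed(self, system, calibration):
        bad = BoundSet({"r_LAC": (0.0, 0.0), "r_ACE": (1.0, 1.0),
                        "r_GLU": (0.1, 0.2), "r_ATP": (20.0, 200.0 / 7.0),
                        "r_TH": (0.0, 0.0)})
        with pytest.raises(InfeasibleError, match="balance|bound"):
            solve_lp(system, calibration.load, bad,
                     ObjectiveSpec("r_TCA", "minimize"))


class TestEnumeration:
    def test_five_scenarios_with_published_groupings(
        self, scenario_table, printed_scenarios
    ):
        """The tight-acetate polytope is a pentagon: five extreme scenarios,
        co-optimal as published (each published row's annotations are a
        subset of the matching cluster's co-optimal set)."""
        assert scenario_table.n_clusters == 5
        for sc in printed_scenarios:
            ci = scenario_table.cluster_of(sc.objective)
            rep = scenario_table.cluster_representative(ci)
            labels = {o.label for o in rep.co_optimal}
            missing = set(sc.cooptimal) - labels
            assert not missing, f"scenario {sc.name}: missing {missing}"

    def test_clusters_match_published_flux_values(
        self, scenario_table, printed_scenarios
    ):
        """Each published row's rounded fluxes agree with the calibrated
        cluster to within printed precision (2 s.f. ~ one unit in the last
        digit, i.e. a few hundredths here)."""
        for sc in printed_scenarios:
            rep = scenario_table.cluster_representative(
                scenario_table.cluster_of(sc.objective))
            for fid in ("r_TCA", "r_PYK", "r_HMP", "r_ME", "r_TA", "r_TK2",
                        "r_ANA"):
                assert rep.fluxes[fid] == pytest.approx(
                    sc.fluxes[fid], abs=0.06), (sc.name, fid)

    def test_every_registry_flux_minimized_and_maximized_once(
        self, scenario_table
    ):
        labels = [r.objective.label for r in scenario_table.records]
        assert len(labels) == len(set(labels)) == 2 * len(mf.REGISTRY_FLUXES)

    def test_degenerate_polytope_collapses_to_one_cluster(self):
        A_ub = np.array([[1.0, 1.0], [-1.0, -1.0],
                         [1.0, -1.0], [-1.0, 1.0]])
        b_ub = np.array([1.0, -1.0, 0.0, 0.0])  # x+y=1, x=y -> a point
        system, load, bounds, xs = polytope_as_system(A_ub, b_ub)
        table = enumerate_scenarios(system, load, bounds, flux_ids=xs)
        assert table.n_clusters == 1

    def test_toy_polytope_matches_brute_force_vertices(self):
        A_ub, b_ub = toy_box()
        verts = enumerate_vertices(A_ub, b_ub)
        system, load, bounds, xs = polytope_as_system(A_ub, b_ub)
        table = enumerate_scenarios(system, load, bounds, flux_ids=xs)
        got = set()
        for ci in range(table.n_clusters):
            rec = table.cluster_representative(ci)
            got.add((round(rec.fluxes["x0"], 6), round(rec.fluxes["x1"], 6)))
        expected = {(round(x, 6), round(y, 6)) for x, y in verts}
        # FVA harvests extreme points; each is a true vertex, and each
        # coordinate extreme is attained
        assert got <= expected
        for j, fid in enumerate(xs):
            lo = min(v[j] for v in verts)
            hi = max(v[j] for v in verts)
            assert any(abs(g[j] - lo) < 1e-6 for g in got)
            assert any(abs(g[j] - hi) < 1e-6 for g in got)


class TestFvaSandwich:
    def test_random_feasible_points_respect_all_extremes(
        self, system, calibration, bounds, scenario_table
    ):
        """Any convex combination of the scenario vertices is feasible and
        lies between the FVA minimum and maximum of every flux."""
        reps = [scenario_table.cluster_representative(ci).fluxes.as_array(system)
                for ci in range(scenario_table.n_clusters)]
        lo = {r.objective.flux_id: r.optimum for r in scenario_table.records
              if r.objective.sense == "minimize"}
        hi = {r.objective.flux_id: r.optimum for r in scenario_table.records
              if r.objective.sense == "maximize"}
        rng = np.random.default_rng(42)
        b = calibration.load.as_array(system.metabolite_order)
        for _ in range(1000):
            w = rng.dirichlet(np.ones(len(reps)))
            r = w @ np.array(reps)
            assert np.max(np.abs(system.A @ r - b)) < 1e-8
            for fid in mf.REGISTRY_FLUXES:
                v = r[system.flux_index(fid)]
                assert lo[fid] - 1e-8 <= v <= hi[fid] + 1e-8


class TestAcetateRelaxation:
    def test_tight_ranges_nest_inside_loose(self, system, calibration, constraints):
        from dataclasses import replace

        tight = mf.build_bounds(constraints)
        loose = mf.build_bounds(replace(constraints, acetate_mode="loose"))
        t = enumerate_scenarios(system, calibration.load, tight)
        l = enumerate_scenarios(system, calibration.load, loose)
        for fid in mf.REGISTRY_FLUXES:
            t_lo = next(r.optimum for r in t.records
                        if r.objective.label == f"MIN {fid}")
            t_hi = next(r.optimum for r in t.records
                        if r.objective.label == f"MAX {fid}")
            l_lo = next(r.optimum for r in l.records
                        if r.objective.label == f"MIN {fid}")
            l_hi = next(r.optimum for r in l.records
                        if r.objective.label == f"MAX {fid}")
            assert l_lo <= t_lo + 1e-8 and t_hi <= l_hi + 1e-8


class TestBiomassEquivalence:
    def test_biomass_maximum_is_the_tca_minimum(
        self, system, calibration, bounds, scenario_table
    ):
        _, same = mf.biomass_max_equivalence(
            system, calibration.load, bounds, scenario_table)
        assert same


class TestNadphBreakdown:
    def test_hand_built_two_to_one_to_one(self, system):
        fv = {f: 0.0 for f in system.flux_order}
        fv.update({"r_HMP": 1.0, "r_TCA": 1.0, "r_ME": 1.0})
        shares = mf.nadph_breakdown(fv, system)
        assert shares == pytest.approx(
            {"r_HMP": 0.5, "r_TCA": 0.25, "r_ME": 0.25, "r_TH": 0.0})

    def test_malic_enzyme_supplies_a_third_at_its_maximum(
        self, system, scenario_table
    ):
        rep = scenario_table.cluster_representative(
            scenario_table.cluster_of("MAX r_ME"))
        shares = mf.nadph_breakdown(rep, system)
        assert shares["r_ME"] == pytest.approx(1 / 3, abs=0.02)
        assert sum(shares.values()) == pytest.approx(1.0)

    def test_zero_malic_enzyme_means_zero_share(self, system, scenario_table):
        rep = scenario_table.cluster_representative(
            scenario_table.cluster_of("MIN r_TCA"))
        assert mf.nadph_breakdown(rep, system)["r_ME"] == 0.0

    def test_no_nadph_production_is_an_error(self, system):
        with pytest.raises(Exception, match="no NADPH"):
            mf.nadph_breakdown({f: 0.0 for f in system.flux_order}, system)


class TestCoOptimalTolerance:
    def test_infinite_tolerance_makes_everything_co_optimal(
        self, system, calibration, bounds
    ):
        table = enumerate_scenarios(system, calibration.load, bounds)
        table = mf.classify_co_optimal(table, system, tol=np.inf)
        n_obj = len(table.records)
        for rec in table.records:
            assert len(rec.co_optimal) == n_obj


class TestCalibration:
    def _printed_from_vertices(self, system, load, bounds, objectives,
                               credit=0.6):
        out = []
        for fid, sense in objectives:
            rec = solve_lp(system, load, bounds, ObjectiveSpec(fid, sense))
            fluxes = {f: rec.fluxes[f] for f in system.flux_order}
            d = derived_fluxes(rec.fluxes, system, nadh_credit=credit)
            fluxes["r_ATP"] = d.r_atp
            out.append(PrintedScenario(
                name=f"{sense[:3]} {fid}", objective=f"{sense[:3]} {fid}",
                fluxes=fluxes))
        return out

    def test_recovers_known_demand_vector_from_noiseless_vertices(
        self, system, bounds, prior_load
    ):
        true = LoadVector(
            mu=0.2, b=dict(prior_load.b), dna_b=dict(prior_load.dna_b),
            nadh_production=0.6)
        printed = self._printed_from_vertices(
            system, true, bounds,
            [("r_TCA", "minimize"), ("r_PYK", "maximize"),
             ("r_ME", "maximize")])
        # deliberately wrong prior; tiny ridge only resolves free directions
        wrong = LoadVector(mu=0.2, b={m: v * 1.3 for m, v in true.b.items()},
                           nadh_production=0.1)
        cal = calibrate_loads(system, bounds, printed, wrong, ridge=1e-5)
        for m, v in true.b.items():
            assert cal.load.b[m] == pytest.approx(v, abs=1e-6), m
        assert cal.nadh_production == pytest.approx(0.6, abs=1e-6)
        assert cal.residual_rms < 1e-8

    def test_consistent_scenarios_leave_zero_residual(
        self, system, bounds, calibration
    ):
        printed = self._printed_from_vertices(
            system, calibration.load, bounds,
            [("r_TCA", "minimize"), ("r_TCA", "maximize")],
            credit=calibration.load.nadh_production)
        cal = calibrate_loads(system, bounds, printed, calibration.load,
                              ridge=1e-6)
        assert cal.residual_rms < 1e-8

    def test_published_calibration_quality(self, calibration):
        """Residuals against the rounded published fluxes sit at the printed
        rounding scale, and the fit does not fall back."""
        assert not calibration.used_fallback
        assert calibration.residual_rms < 0.05
        assert calibration.residual_max < 0.1
        assert 0.3 < calibration.nadh_production < 1.0

    def test_free_directions_are_reported(self, calibration):
        # the glycolytic chain splits are unidentifiable from printed rows
        assert "OAA" in calibration.free_directions
        assert "AKG" in calibration.free_directions
        assert "P5P" not in calibration.free_directions
        assert "NADPH" not in calibration.free_directions

    def test_predicts_the_withheld_pyk_maximum(
        self, system, bounds, constraints, prior_load
    ):
        """Calibrating on published scenarios 1, 2 and 5 predicts the
        pyruvate-kinase flux maximum 0.93 printed in the text."""
        printed = [s for s in mf.load_printed_scenarios(constraints=constraints)
                   if s.name in ("1", "2", "5")]
        cal = calibrate_loads(system, bounds, printed, prior_load)
        rec = solve_lp(system, cal.load, bounds,
                       ObjectiveSpec("r_PYK", "maximize"))
        assert rec.optimum == pytest.approx(0.93, abs=0.01)

    def test_fewer_than_two_scenarios_rejected(self, system, bounds, prior_load):
        with pytest.raises(Exception, match="two printed scenarios"):
            calibrate_loads(system, bounds, [], prior_load)


class TestDnaRobustness:
    def test_cluster_count_survives_three_fold_dna_load(
        self, system, bounds, prior_load
    ):
        base = enumerate_scenarios(system, prior_load, bounds)
        scaled = enumerate_scenarios(
            system, mf.scale_dna_load(prior_load, 3.0), bounds)
        assert scaled.n_clusters == base.n_clusters


class TestRandomPolytopeOracle:
    @pytest.mark.parametrize("seed", range(8))
    def test_fva_extremes_match_vertex_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        d = int(rng.integers(2, 5))
        A_ub, b_ub = box_cut_polytope(d, int(rng.integers(1, 4)), rng)
        verts = enumerate_vertices(A_ub, b_ub)
        assert len(verts) >= d + 1
        system, load, bounds, xs = polytope_as_system(A_ub, b_ub)
        table = enumerate_scenarios(system, load, bounds, flux_ids=xs)
        for j, fid in enumerate(xs):
            lo = next(r.optimum for r in table.records
                      if r.objective.label == f"MIN {fid}")
            hi = next(r.optimum for r in table.records
                      if r.objective.label == f"MAX {fid}")
            assert lo == pytest.approx(verts[:, j].min(), abs=1e-8)
            assert hi == pytest.approx(verts[:, j].max(), abs=1e-8)
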
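import numpy as np
import pytest

import mipflux as mf
from mipflux.network import (
    COFACTORS,
    Metabolite,
    NetworkError,
    Reaction,
    assemble_system,
    carbon_closure,
    degrees_of_freedom,
    derived_fluxes,
    parse_metabolites,
    parse_network,
)

from oracles import exact_rank


def toy_chain():
    """A -> B -> C with only B balanced."""
    mets = [Metabolite("A", 1, False), Metabolite("B", 1, True),
            Metabolite("C", 1, False)]
    rxns = [Reaction("r1", {"A": -1, "B": 1}, False),
            Reaction("r2", {"B": -1, "C": 1}, False)]
    return rxns, mets


class TestParsing:
    def test_bundled_network_has_the_named_fluxes(self, system):
        for fid in mf.REGISTRY_FLUXES:
            assert fid in system.flux_order
        # plus uptake/PDH/interconversion/transhydrogenase machinery
        for fid in ("r_PGI", "r_PFK", "r_EMP", "r_PDH", "r_AKGD", "r_MDH", "r_TH"):
            assert fid in system.flux_order

    def test_unknown_metabolite_is_rejected_with_line(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text(
            "id\tequation\treversible\tATP\tNADH\tNADPH\tFADH2\tCO2\n"
            "r1\tG6P -> BOGUS\t0\t0\t0\t0\t0\t0\n"
        )
        with pytest.raises(NetworkError, match="line 2.*BOGUS"):
            parse_network(p)

    def test_carbon_imbalance_is_rejected_by_reaction(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text(
            "id\tequation\treversible\tATP\tNADH\tNADPH\tFADH2\tCO2\n"
            "r1\tG6P -> GAP\t0\t0\t0\t0\t0\t0\n"
        )
        with pytest.raises(NetworkError, match="r1.*carbon"):
            parse_network(p)

    def test_empty_reaction_list_is_an_error(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("id\tequation\treversible\tATP\tNADH\tNADPH\tFADH2\tCO2\n")
        with pytest.raises(NetworkError, match="no reactions"):
            parse_network(p)

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text(
            "id\tequation\treversible\tATP\tNADH\tNADPH\tFADH2\tCO2\n"
            "r1\tG6P -> F6P\t0\t0\t0\t0\t0\t0\n"
            "r1\tF6P -> G6P\t0\t0\t0\t0\t0\t0\n"
        )
        with pytest.raises(NetworkError, match="duplicate"):
            parse_network(p)

    def test_every_bundled_reaction_balances_carbon(self):
        # parse_network validates; reaching here means all reactions balance
        reactions, mets = parse_network()
        assert len(reactions) == 18


class TestAssembly:
    def test_toy_chain_gives_one_row(self):
        system = assemble_system(*toy_chain())
        assert system.A.shape == (1, 2)
        assert system.A.tolist() == [[1.0, -1.0]]

    def test_declaration_order_permutation_permutes_columns(self):
        rxns, mets = toy_chain()
        s1 = assemble_system(rxns, mets)
        s2 = assemble_system(rxns[::-1], mets)
        perm = [s2.flux_order.index(f) for f in s1.flux_order]
        assert np.array_equal(s1.A, s2.A[:, perm])

    def test_balanced_metabolites_only(self, system):
        assert "GLC" not in system.metabolite_order
        assert "ACE_EX" not in system.metabolite_order
        assert "NADPH" in system.metabolite_order
        assert system.A.shape == (13, 18)


class TestDegreesOfFreedom:
    def test_measured_phenotype_leaves_two(self, system):
        assert degrees_of_freedom(system) == 2

    def test_dropping_the_acetate_equality_gives_three(self, system):
        assert degrees_of_freedom(system, ("r_LAC", "r_TH")) == 3

    def test_matches_exact_row_reduction_oracle(self, system):
        for eqs in (("r_LAC", "r_ACE", "r_TH"), ("r_LAC", "r_TH"), ()):
            rows = [system.A]
            for fid in eqs:
                e = np.zeros((1, system.n_fluxes))
                e[0, system.flux_index(fid)] = 1.0
                rows.append(e)
            expected = system.n_fluxes - exact_rank(np.vstack(rows))
            assert degrees_of_freedom(system, eqs) == expected

    def test_fully_determined_chain_has_none(self):
        rxns, mets = toy_chain()
        system = assemble_system(rxns, mets)
        assert degrees_of_freedom(system, ("r1",)) == 0


class TestDerivedFluxes:
    def test_zero_fluxes_give_zero_totals(self, system):
        d = derived_fluxes({f: 0.0 for f in system.flux_order}, system)
        assert d.r_co2 == d.r_atp == d.nadh == d.nadph == d.fadh2 == 0.0

    def test_one_tca_turn_bookkeeping(self, system):
        """One full cycle: AcCoA in, 2 CO2, 2 NADH + 1 NADPH + 1 FADH2 + 1 GTP.

        With NADP-linked isocitrate dehydrogenase the oxidative ATP is
        2 x 2.0 + 1 x 1.0 = 5 plus the substrate-level GTP.
        """
        fv = {f: 0.0 for f in system.flux_order}
        fv.update({"r_TCA": 1.0, "r_AKGD": 1.0, "r_MDH": 1.0})
        d = derived_fluxes(fv, system, po_nadh=2.0, po_fadh=1.0)
        assert d.nadh == 2.0
        assert d.nadph == 1.0
        assert d.fadh2 == 1.0
        assert d.atp_substrate_level == 1.0
        assert d.r_co2 == 2.0
        assert d.r_atp == pytest.approx(1.0 + 2 * 2.0 + 1 * 1.0)

    def test_scenario_one_reaches_the_atp_floor(
        self, system, scenario_table, calibration
    ):
        """The yield-optimal scenario produces ATP right at the lower bound
        (Y_X/ATP = 10 at mu = 0.2 corresponds to 20 mmol ATP/g h)."""
        rec = scenario_table.cluster_representative(
            scenario_table.cluster_of("MIN r_TCA"))
        d = derived_fluxes(rec.fluxes, system,
                           nadh_credit=calibration.load.nadh_production)
        assert d.r_atp == pytest.approx(20.0, abs=1e-6)

    def test_missing_flux_raises(self, system):
        with pytest.raises(KeyError):
            derived_fluxes({"r_GLU": 1.0}, system)

    def test_linear_in_fluxes(self, system):
        rng = np.random.default_rng(1)
        a = dict(zip(system.flux_order, rng.uniform(0, 2, system.n_fluxes)))
        b = dict(zip(system.flux_order, rng.uniform(0, 2, system.n_fluxes)))
        summed = {f: a[f] + b[f] for f in system.flux_order}
        da, db, ds = (derived_fluxes(v, system) for v in (a, b, summed))
        assert ds.r_atp == pytest.approx(da.r_atp + db.r_atp)
        assert ds.r_co2 == pytest.approx(da.r_co2 + db.r_co2)


class TestConservation:
    def test_solutions_satisfy_mass_balance(self, system, calibration, scenario_table):
        b = calibration.load.as_array(system.metabolite_order)
        scale = max(1.0, float(np.max(np.abs(b))))
        for rec in scenario_table.records:
            r = rec.fluxes.as_array(system)
            assert np.max(np.abs(system.A @ r - b)) <= 1e-6 * scale

    def test_carbon_closes_for_every_scenario(self, system, calibration, scenario_table):
        demands = {m: v for m, v in calibration.load.b.items() if m != "NADPH"}
        for rec in scenario_table.records:
            assert carbon_closure(rec.fluxes, system, demands) == pytest.approx(
                0.0, abs=1e-6)
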
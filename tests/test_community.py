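"""Community model construction, FBA/FVA and the net-secretion readout."""

import numpy as np
import pandas as pd
import pytest

import fluxpattern as fp
from fluxpattern.community import (
    Metabolite,
    Reaction,
    Reconstruction,
    effective_community_stoichiometry,
)
from fluxpattern.errors import (
    InfeasibleModelError,
    MissingModelError,
    StoichiometryConflictError,
)
from oracles import fva_by_vertex_enumeration


def _strain(suffix, extra_reactions=(), biomass_coef=-1.0):
    mets = [Metabolite("glc", "e"), Metabolite("glc_c", "c")]
    rxns = [
        Reaction("EX_glc", {"glc": -1.0}, -1000.0, 1000.0),
        Reaction("T_glc", {"glc": -1.0, "glc_c": 1.0}, 0.0, 1000.0),
        Reaction("BIOMASS", {"glc_c": biomass_coef}, 0.0, 1000.0),
        *extra_reactions,
    ]
    return Reconstruction(id=f"S{suffix}", metabolites=mets, reactions=rxns,
                          biomass_reaction="BIOMASS",
                          exchange_reactions=["EX_glc"])


class TestPanModel:
    def test_single_member_is_identity(self, toy_recons):
        pan = fp.build_pan_model([toy_recons["M1"]])
        assert {r.id for r in pan.reactions} == {r.id for r in toy_recons["M1"].reactions}
        assert pan.reaction("BIOMASS").stoichiometry == \
            toy_recons["M1"].reaction("BIOMASS").stoichiometry

    def test_union_of_disjoint_reactions(self):
        a = _strain("a")
        extra = Reaction("SIDE", {"glc_c": -1.0}, 0.0, 5.0)
        b = _strain("b", extra_reactions=(extra,))
        pan = fp.build_pan_model([a, b])
        assert "SIDE" in {r.id for r in pan.reactions}

    def test_biomass_coefficients_are_averaged(self):
        pan = fp.build_pan_model([_strain("a", biomass_coef=-1.0),
                                  _strain("b", biomass_coef=-3.0)])
        assert pan.reaction("BIOMASS").stoichiometry["glc_c"] == pytest.approx(-2.0)

    def test_merged_bounds_take_the_widest_interval(self):
        a = _strain("a")
        b = _strain("b")
        a.reaction("T_glc").upper = 10.0
        b.reaction("T_glc").lower = -5.0
        pan = fp.build_pan_model([a, b])
        assert pan.reaction("T_glc").lower == -5.0
        assert pan.reaction("T_glc").upper == 1000.0

    def test_conflicting_stoichiometry_is_an_error(self):
        a = _strain("a")
        b = _strain("b")
        b.reaction("T_glc").stoichiometry = {"glc": -2.0, "glc_c": 1.0}
        with pytest.raises(StoichiometryConflictError, match="T_glc"):
            fp.build_pan_model([a, b])


class TestBuildCommunity:
    def test_single_microbe_community_biomass_equals_member_biomass(self, toy_recons):
        model = fp.build_community_model({"M1": 1.0}, toy_recons)
        eff = effective_community_stoichiometry(model)
        assert eff == {"M1__glc_c": -1.0}

    def test_two_microbe_biomass_weighting(self, toy_recons):
        model = fp.build_community_model({"M1": 0.6, "M2": 0.4}, toy_recons)
        eff = effective_community_stoichiometry(model)
        # 0.6 * (M1: -1 glc_c) + 0.4 * (M2: -0.5 glc_c, -0.5 ac_c)
        assert eff["M1__glc_c"] == pytest.approx(-0.6)
        assert eff["M2__glc_c"] == pytest.approx(-0.2)
        assert eff["M2__ac_c"] == pytest.approx(-0.2)

    def test_two_coupling_rows_per_exchange(self, toy_recons):
        model = fp.build_community_model({"M1": 0.5, "M3": 0.5}, toy_recons)
        m1_couples = [c for c in model.coupling if c[0].startswith("M1__")]
        assert len(m1_couples) == 2  # M1 has two exchanges
        _, _, A_c = model.matrices()
        assert A_c.shape[0] == 2 * len(model.coupling)

    def test_zero_abundance_microbe_is_excluded(self, toy_recons):
        with_zero = fp.build_community_model({"M1": 1.0, "M2": 0.0}, toy_recons)
        without = fp.build_community_model({"M1": 1.0}, toy_recons)
        assert {r.id for r in with_zero.reactions} == {r.id for r in without.reactions}

    def test_missing_reconstruction_raises(self, toy_recons):
        with pytest.raises(MissingModelError, match="M9"):
            fp.build_community_model({"M9": 1.0}, toy_recons)

    def test_negative_abundance_raises(self, toy_recons):
        with pytest.raises(ValueError):
            fp.build_community_model({"M1": 1.2, "M2": -0.2}, toy_recons)

    def test_every_lumen_metabolite_has_both_sinks(self, toy_recons):
        model = fp.build_community_model({"M1": 0.5, "M2": 0.3, "M3": 0.2}, toy_recons)
        assert set(model.diet_sinks) == set(model.fecal_sinks) == {"glc", "but", "ac"}


class TestDiet:
    def test_diet_opens_sink_to_minus_supply(self, toy_recons):
        model = fp.build_community_model({"M1": 1.0}, toy_recons)
        fed = fp.apply_diet(model, {"glc": 10.0})
        sink = fed.reaction(fed.diet_sinks["glc"])
        assert (sink.lower, sink.upper) == (-10.0, 0.0)
        # original untouched
        assert model.reaction(model.diet_sinks["glc"]).lower == 0.0

    def test_unknown_diet_metabolite_skipped_with_warning(self, toy_recons, caplog):
        model = fp.build_community_model({"M1": 1.0}, toy_recons)
        with caplog.at_level("WARNING"):
            fed = fp.apply_diet(model, {"xylose": 5.0})
        assert "xylose" in caplog.text
        assert all(fed.reaction(r).lower == 0.0 for r in fed.diet_sinks.values())

    def test_negative_supply_rejected(self, toy_recons):
        model = fp.build_community_model({"M1": 1.0}, toy_recons)
        with pytest.raises(ValueError):
            fp.apply_diet(model, {"glc": -1.0})


class TestFBA:
    def test_toy_m1_biomass_optimum(self, m1_community):
        assert fp.solve_community_fba(m1_community) == pytest.approx(1.0, abs=1e-9)

    def test_empty_diet_is_infeasible(self, toy_recons):
        model = fp.build_community_model({"M1": 1.0}, toy_recons)
        with pytest.raises(InfeasibleModelError):
            fp.solve_community_fba(fp.apply_diet(model, {}))

    def test_micro_lp_single_path(self, toy_recons):
        """A one-substrate chain can only push as much biomass as the diet
        supplies divided by the biomass requirement."""
        model = fp.build_community_model(
            {"M1": 1.0}, toy_recons, biomass_bounds=(0.0, 1000.0))
        fed = fp.apply_diet(model, {"glc": 0.7})
        assert fp.solve_community_fba(fed) == pytest.approx(0.7, abs=1e-9)


class TestFVA:
    def test_toy_m1_butyrate_worked_example(self, m1_community):
        w = fp.solve_community_fba(m1_community)
        fva = fp.fva_exchange_bounds(m1_community, "but", w)
        assert fva == pytest.approx((0.0, 0.0, 0.0, 9.0), abs=1e-7)
        assert fp.net_secretion_capacity(*fva) == pytest.approx((9.0, 0.0), abs=1e-7)

    def test_unknown_metabolite_raises(self, m1_community):
        with pytest.raises(KeyError):
            fp.fva_exchange_bounds(m1_community, "xylose", 1.0)

    def test_untransportable_metabolite_is_all_zero(self, toy_recons):
        """M1 cannot move acetate, so with M1 alone every acetate sink flux
        is blocked ... acetate is not even in the lumen; use M2+M3 with
        butyrate instead: M2 alone cannot transport butyrate."""
        model = fp.build_community_model({"M2": 1.0}, toy_recons)
        fed = fp.apply_diet(model, {"glc": 10.0})
        w = fp.solve_community_fba(fed)
        assert "but" not in fed.diet_sinks  # not transportable -> not in lumen
        fva = fp.fva_exchange_bounds(fed, "ac", w)
        assert fva[0] == 0.0 and fva[1] == 0.0  # no acetate in the diet

    def test_matches_vertex_enumeration_single_microbe(self, m1_community):
        w = fp.solve_community_fba(m1_community)
        for met in ("glc", "but"):
            for sinks in (m1_community.diet_sinks, m1_community.fecal_sinks):
                rid = sinks[met]
                lo, hi = fva_by_vertex_enumeration(m1_community, rid, w)
                fva = fp.fva_exchange_bounds(m1_community, met, w)
                if sinks is m1_community.diet_sinks:
                    got = (fva[0], fva[1])
                else:
                    got = (fva[2], fva[3])
                assert got[0] == pytest.approx(lo, abs=1e-6)
                assert got[1] == pytest.approx(hi, abs=1e-6)

    def test_interval_contained_in_bound_box(self, m1_community):
        w = fp.solve_community_fba(m1_community)
        for met in ("glc", "but"):
            fva = fp.fva_exchange_bounds(m1_community, met, w)
            d = m1_community.reaction(m1_community.diet_sinks[met])
            f = m1_community.reaction(m1_community.fecal_sinks[met])
            assert d.lower - 1e-9 <= fva[0] <= fva[1] <= d.upper + 1e-9
            assert f.lower - 1e-9 <= fva[2] <= fva[3] <= f.upper + 1e-9

    def test_added_constraint_never_widens_an_interval(self, m1_community):
        """FVA nestedness: tightening any reaction bound can only shrink the
        feasible interval of every other reaction."""
        import copy

        w = fp.solve_community_fba(m1_community)
        base = fp.fva_exchange_bounds(m1_community, "but", w)
        tighter = copy.deepcopy(m1_community)
        tighter.reaction("M1__FERM").upper = 5.0
        got = fp.fva_exchange_bounds(tighter, "but", w)
        assert got[2] >= base[2] - 1e-9 and got[3] <= base[3] + 1e-9

    def test_coupling_forces_inactive_microbe_fluxes_to_zero(self, toy_recons):
        """If a microbe's biomass flux is pinned at 0, coupling makes all its
        lumen exchanges carry zero flux."""
        model = fp.build_community_model({"M1": 0.5, "M2": 0.5}, toy_recons,
                                         biomass_bounds=(0.0, 1000.0))
        fed = fp.apply_diet(model, {"glc": 10.0})
        fed.reaction("M2__BIOMASS").upper = 0.0
        w = fp.solve_community_fba(fed)
        from fluxpattern.community import _solve_lp

        for rid in ("M2__IEX_glc", "M2__IEX_ac"):
            obj = np.zeros(len(fed.reactions))
            obj[fed._rxn_index[rid]] = 1.0
            for sense in ("min", "max"):
                _, val, _ = _solve_lp(fed, obj, sense,
                                      fixed={fed.community_biomass: (w, w)})
                assert abs(val) <= 1e-7

    def test_scaling_diet_up_never_decreases_max_faecal(self, toy_recons):
        model = fp.build_community_model({"M1": 0.6, "M2": 0.4}, toy_recons)
        for lam in (1.0, 2.0, 5.0):
            base = fp.apply_diet(model, {"glc": 10.0})
            more = fp.apply_diet(model, {"glc": 10.0 * lam})
            w1, w2 = fp.solve_community_fba(base), fp.solve_community_fba(more)
            for met in ("but", "ac"):
                f1 = fp.fva_exchange_bounds(base, met, w1)
                f2 = fp.fva_exchange_bounds(more, met, w2)
                assert f2[3] >= f1[3] - 1e-7


class TestNetSecretion:
    @pytest.mark.parametrize(
        "fva, expected",
        [
            ((-4.0, 0.0, 0.0, 6.0), (2.0, 0.0)),
            ((-4.0, -1.0, 2.0, 6.0), (2.0, 1.0)),
            ((0.0, 0.0, 0.0, 0.0), (0.0, 0.0)),
            ((0.0, 0.0, 0.0, 9.0), (9.0, 0.0)),
        ],
    )
    def test_capacity_arithmetic(self, fva, expected):
        assert fp.net_secretion_capacity(*fva) == pytest.approx(expected)

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValueError):
            fp.net_secretion_capacity(1.0, 0.0, 0.0, 0.0)


@pytest.fixture(scope="module")
def abundance_table():
    rows = [
        {"M1": 0.5, "M2": 0.3, "M3": 0.2},
        {"M1": 0.5, "M2": 0.3, "M3": 0.2},  # duplicate of sample 0
        {"M1": 1.0, "M2": 0.0, "M3": 0.0},
        {"M1": 0.2, "M2": 0.8, "M3": 0.0},
    ]
    return pd.DataFrame(rows, index=["s0", "s1", "s2", "s3"]).fillna(0.0)


class TestPopulationProfiles:

    def test_identical_samples_get_identical_profiles(self, toy_recons, abundance_table):
        flux, stats = fp.population_flux_profiles(
            abundance_table, toy_recons, {"glc": 10.0})
        assert len(flux) == 4
        np.testing.assert_allclose(flux.loc["s0"], flux.loc["s1"], atol=1e-9)
        assert np.all(stats["w"].between(0.4, 1.0 + 1e-9))

    def test_zero_abundance_equals_absent_species(self, toy_recons, abundance_table):
        flux, _ = fp.population_flux_profiles(
            abundance_table, toy_recons, {"glc": 10.0})
        only_m1 = pd.DataFrame([{"M1": 1.0}], index=["x"])
        flux2, _ = fp.population_flux_profiles(only_m1, toy_recons, {"glc": 10.0})
        shared = [c for c in flux.columns if c in flux2.columns]
        np.testing.assert_allclose(
            flux.loc["s2", shared].to_numpy(dtype=float),
            flux2.loc["x", shared].to_numpy(dtype=float), atol=1e-9)

    def test_population_run_equals_per_sample_oracle(self, toy_recons):
        rng = np.random.default_rng(123)
        raw = rng.dirichlet([2.0, 2.0, 2.0], size=20)
        table = pd.DataFrame(raw, columns=["M1", "M2", "M3"],
                             index=[f"p{i}" for i in range(20)])
        diet = {"glc": 10.0}
        flux, stats = fp.population_flux_profiles(table, toy_recons, diet)
        assert len(flux) == 20
        for sample in ["p0", "p7", "p19"]:
            abunds = {m: v for m, v in table.loc[sample].items() if v > 0}
            model = fp.apply_diet(fp.build_community_model(abunds, toy_recons), diet)
            w = fp.solve_community_fba(model)
            assert stats.loc[sample, "w"] == pytest.approx(w, abs=1e-9)
            for met in flux.columns:
                fva = fp.fva_exchange_bounds(model, met, w)
                prod, _ = fp.net_secretion_capacity(*fva)
                assert flux.loc[sample, met] == pytest.approx(prod, abs=1e-7)

    def test_failing_sample_dropped_not_fatal(self, toy_recons, caplog):
        table = pd.DataFrame(
            [{"M1": 1.0, "M3": 0.0}, {"M1": 0.0, "M3": 1.0}],  # M3 can't grow on glc
            index=["ok", "bad"])
        with caplog.at_level("WARNING"):
            flux, _ = fp.population_flux_profiles(table, toy_recons, {"glc": 10.0})
        assert list(flux.index) == ["ok"]
        assert "bad" in caplog.text
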
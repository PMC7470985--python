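import numpy as np
import pytest

from overflux.fba import (
    FBAStatus,
    MediaSpec,
    ModelMetabolite,
    Reaction,
    StoichiometricModel,
    default_media,
    flux_change_label,
    knockout,
    media_grid,
    solve_fba,
    validate_model,
)

HG_MEDIA = MediaSpec({"glc": 2.78, "nh3": 10, "co2": 10})

NAMED_ENZYMES = [
    "pyruvate kinase", "pyruvate carboxylase", "pyruvate synthase",
    "pyruvate dehydrogenase", "acetate kinase", "phosphotransacetylase",
    "pyruvate phosphate dikinase", "malate dehydrogenase",
    "serine ammonia-lyase", "formate-tetrahydrofolate ligase",
    "lactate dehydrogenase", "succinyl-CoA synthetase",
    "aspartate aminotransferase", "aspartate oxidase",
    "pyruvate formate-lyase", "asparagine synthetase",
    "aspartate ammonium ligase",
]


def toy_chain_model(bound=2.0):
    """uptake -> convert -> sink, with the conversion bounded."""
    return StoichiometricModel(
        name="chain",
        metabolites=[
            ModelMetabolite("a_e", "e"), ModelMetabolite("a", "c"),
            ModelMetabolite("b", "c"),
        ],
        reactions=[
            Reaction("EX_a", {"a_e": -1}, -1000, 1000),
            Reaction("At", {"a_e": -1, "a": 1}, 0, 1000),
            Reaction("CONV", {"a": -1, "b": 1}, 0, bound),
            Reaction("SINK", {"b": -1}, 0, 1000),
        ],
        objective="SINK",
    )


class TestSolveFBA:
    def test_empty_media_grows_nothing(self, model):
        res = solve_fba(model, MediaSpec({}))
        assert res.ok and res.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_toy_chain_is_bound_limited(self):
        res = solve_fba(toy_chain_model(bound=2.0), MediaSpec({"a": 10}))
        assert res.objective_value == pytest.approx(2.0, abs=1e-9)

    def test_steady_state_holds_at_optimum(self, model):
        res = solve_fba(model, HG_MEDIA)
        S = model.stoichiometric_matrix()
        v = np.array([res.reaction_fluxes[r.id] for r in model.reactions])
        assert np.abs(S @ v).max() < 1e-9

    def test_halved_glucose_cannot_grow_more(self, model):
        full = solve_fba(model, HG_MEDIA)
        half = solve_fba(model, MediaSpec({"glc": 1.39, "nh3": 10, "co2": 10}))
        assert half.objective_value <= full.objective_value + 1e-9

    def test_repeat_solve_bit_identical(self, model):
        r1 = solve_fba(model, HG_MEDIA)
        r2 = solve_fba(model, HG_MEDIA)
        assert r1.reaction_fluxes == r2.reaction_fluxes

    def test_acetate_and_formate_alone_yield_no_growth(self, model):
        res = solve_fba(model, MediaSpec({"ac": 10, "for": 10, "nh3": 10, "co2": 10}))
        assert res.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_bounds_reported(self):
        m = toy_chain_model()
        # force the sink while closing the uptake: unsatisfiable
        m.reactions[3] = Reaction("SINK", {"b": -1}, 5.0, 1000)
        m.reactions[0] = Reaction("EX_a", {"a_e": -1}, 0, 0)
        m.__post_init__()
        res = solve_fba(m)
        assert res.status is FBAStatus.infeasible and not res.reaction_fluxes

    def test_objective_agrees_with_cobra_oracle(self, model):
        cobra = pytest.importorskip("cobra")
        cm = cobra.Model("oracle")
        mets = {m.id: cobra.Metabolite(m.id) for m in model.metabolites}
        bounded = [
            (r, (-HG_MEDIA.get(list(r.stoichiometry)[0].removesuffix("_e"), 0.0),
                 r.upper_bound) if r.is_exchange else (r.lower_bound, r.upper_bound))
            for r in model.reactions
        ]
        for r, bounds in bounded:
            rx = cobra.Reaction(r.id)
            cm.add_reactions([rx])
            rx.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()})
            rx.bounds = bounds
        cm.objective = model.objective
        expected = cm.optimize().objective_value
        res = solve_fba(model, HG_MEDIA)
        assert res.objective_value == pytest.approx(expected, abs=1e-8)


class TestMediaGrid:
    @pytest.fixture(scope="class")
    @staticmethod
    def grid(model):
        return media_grid(model)

    def test_biomass_invariant_across_high_glucose_conditions(self, grid):
        hg = [r.objective_value for c, r in grid.results.items() if c[0] == "high"]
        assert len(hg) == 4
        assert max(hg) - min(hg) < 1e-9

    def test_low_glucose_grows_less_than_high(self, grid):
        lg = grid.results[("low", False, False)].objective_value
        hg = grid.results[("high", False, False)].objective_value
        assert 0 < lg < hg

    def test_all_zero_grid_grows_nothing(self, model):
        grid = media_grid(
            model, base_media={}, glucose_uptake={"high": 0.0, "low": 0.0},
            supplement_uptake=0.0,
        )
        assert all(
            r.objective_value == pytest.approx(0.0, abs=1e-9)
            for r in grid.results.values()
        )

    def test_delta_tables_label_every_reaction(self, grid, model):
        delta = grid.deltas[("low", True, False)]
        assert set(delta["reaction"]) == {r.id for r in model.reactions}
        assert set(delta["label"]) <= {
            "increased", "decreased", "zero_net", "direction_change", "no_change"
        }

    def test_grid_reruns_bit_identical(self, model, grid):
        again = media_grid(model)
        for cond, res in grid.results.items():
            assert res.reaction_fluxes == again.results[cond].reaction_fluxes


class TestFluxChangeLabel:
    @pytest.mark.parametrize(
        "v0, v1, label",
        [
            (1.0, 2.0, "increased"),
            (2.0, 1.0, "decreased"),
            (1.0, 0.0, "zero_net"),
            (1.0, -1.0, "direction_change"),
            (-3.74, -0.122, "decreased"),
            (0.0, 0.0, "no_change"),
        ],
    )
    def test_labels(self, v0, v1, label):
        assert flux_change_label(v0, v1) == label


class TestKnockout:
    def test_either_asparagine_route_is_interchangeable(self, model):
        base = solve_fba(model, HG_MEDIA)
        for rid in ("ASNL", "ASNS"):
            ko = solve_fba(knockout(model, rid), HG_MEDIA)
            assert abs(ko.objective_value - base.objective_value) < 1e-9
            for ex, flux in base.exchange_fluxes.items():
                assert abs(ko.exchange_fluxes[ex] - flux) < 1e-9

    def test_both_asparagine_routes_knocked_out_stops_growth(self, model):
        res = solve_fba(knockout(model, ["ASNL", "ASNS"]), HG_MEDIA)
        assert res.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_biomass_knockout_gives_zero_objective(self, model):
        res = solve_fba(knockout(model, "BIOMASS"), HG_MEDIA)
        assert res.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_unknown_reaction_rejected(self, model):
        with pytest.raises(KeyError):
            knockout(model, "NOT_A_REACTION")

    def test_monotone_under_bound_relaxation(self, model):
        rng = np.random.default_rng(17)
        base = solve_fba(model, HG_MEDIA)
        from overflux.fba import apply_media

        constrained = apply_media(model, HG_MEDIA)
        internal = [r for r in constrained.reactions if not r.is_exchange]
        for _ in range(20):
            relaxed = constrained.copy()
            for r in rng.choice(len(internal), size=5, replace=False):
                rxn = internal[r]
                j = relaxed._rxn_index[rxn.id]
                relaxed.reactions[j] = Reaction(
                    rxn.id, rxn.stoichiometry,
                    rxn.lower_bound * (2 if rxn.lower_bound < 0 else 1),
                    rxn.upper_bound * 2, rxn.name, rxn.exempt_balance,
                )
            res = solve_fba(relaxed)
            assert res.objective_value >= base.objective_value - 1e-9


class TestValidateModel:
    def test_shipped_model_has_zero_violations(self, model):
        report = validate_model(model)
        assert report.violations == []
        assert report.warnings == []

    def test_shipped_model_contains_the_expected_enzymes(self, model):
        names = " | ".join(r.name.lower() for r in model.reactions)
        for enzyme in NAMED_ENZYMES:
            assert enzyme.split(" (")[0].lower() in names, enzyme

    def test_carbon_imbalance_detected(self, model):
        broken = model.copy()
        j = broken._rxn_index["PDH"]
        broken.reactions[j] = Reaction(
            "PDH", {"pyr": -1, "nad": -1, "accoa": 1, "nadh": 1}, 0, 1000
        )
        report = validate_model(broken)
        assert any("PDH" in v and "carbon" in v for v in report.violations)

    def test_isolated_metabolite_is_dead_end_warning(self, model):
        lonely = model.copy()
        lonely.metabolites = lonely.metabolites + [
            ModelMetabolite("orphan", "c", carbon=1)
        ]
        lonely.__post_init__()
        report = validate_model(lonely)
        assert any("orphan" in w for w in report.warnings)
        assert report.ok

    def test_inverted_bounds_are_violation(self):
        m = toy_chain_model()
        m.reactions[2] = Reaction("CONV", {"a": -1, "b": 1}, 5, 2)
        m.__post_init__()
        assert not validate_model(m).ok
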
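"""Medium-to-bounds translation and growth predictions across media."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mucimin.fba import InfeasibleError, optimize
from mucimin.media import (
    MediumComponent,
    MediumError,
    MediumSpec,
    MissingExchangeError,
    apply_medium,
    compare_flux_distributions,
    essentiality_scan,
    growth_table,
    predict_growth,
    uptake_scan,
)
from mucimin.synth import DEACETYLASE_ID, ToyModelSpec, make_toy_model


def chain_medium(budget=10.0):
    return MediumSpec("a", (MediumComponent("a_e", "sugar"),), sugar_budget=budget)


class TestApplyMedium:
    def test_single_sugar_gets_full_budget(self, core_v2, media):
        m = apply_medium(core_v2, media["glucose"])
        assert m.reaction("EX_glc").lower_bound == -10.0
        # every other uptake is closed, secretion stays open
        for rid in m.exchange_ids():
            r = m.reaction(rid)
            assert r.upper_bound == 1000.0
            if rid not in ("EX_glc", "EX_thr", "EX_gln", "EX_h2o"):
                assert r.lower_bound == 0.0

    def test_category_bounds(self, core_v2, media):
        m = apply_medium(core_v2, media["glcnac"])
        assert m.reaction("EX_gln").lower_bound == -1000.0  # non-limiting
        assert m.reaction("EX_thr").lower_bound == -1.0  # limited uptake
        assert m.reaction("EX_glcnac").lower_bound == -10.0  # sugar budget

    def test_two_sugars_split_budget_equally(self, core_v2, media):
        m = apply_medium(core_v2, media["glcnac_glucose"])
        assert m.reaction("EX_glcnac").lower_bound == -5.0
        assert m.reaction("EX_glc").lower_bound == -5.0

    def test_empty_medium_closes_all_uptake(self, core_v2):
        empty = MediumSpec("empty", ())
        m = apply_medium(core_v2, empty)
        assert all(m.reaction(r).lower_bound == 0.0 for r in m.exchange_ids())
        assert optimize(m).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_missing_exchange_lists_offender(self, core_v2, media):
        with pytest.raises(MissingExchangeError, match="glcn_e"):
            apply_medium(core_v2, media["glcn"])

    def test_idempotent_and_component_order_independent(self, core_v2, media):
        from mucimin.model import models_equal

        spec = media["glcnac_glucose"]
        once = apply_medium(core_v2, spec)
        twice = apply_medium(once, spec)
        assert models_equal(once, twice)
        shuffled = MediumSpec(spec.name, tuple(reversed(spec.components)),
                              spec.sugar_budget)
        assert models_equal(once, apply_medium(core_v2, shuffled))


class TestPredictGrowth:
    def test_glucose_only_fails_without_amination(self, core_v2, media):
        assert not predict_growth(core_v2, media["glucose"]).grows

    def test_glcnac_supports_growth(self, core_v2, media):
        pred = predict_growth(core_v2, media["glcnac"])
        assert pred.grows and pred.mu_au > 1.0

    def test_glcn_transporter_rescues_glcn_media(self, core_v2, core_v2_glcn, media):
        assert not predict_growth(core_v2, media["glucose_glcn"],
                                  on_missing="flag").grows
        assert predict_growth(core_v2_glcn, media["glucose_glcn"]).grows
        assert predict_growth(core_v2_glcn, media["glcn"]).grows

    def test_flagged_missing_component_reported(self, core_v2, media):
        pred = predict_growth(core_v2, media["glcn"], on_missing="flag")
        assert pred.missing_exchanges == ("glcn_e",)
        assert pred.no_route and not pred.grows


class TestGrowthTable:
    def test_v1_v2_disagree_on_glucose_only(self, core_v1, core_v2, media):
        order = ["glucose_glcn", "glcn", "glcnac", "glcnac_glucose", "galnac",
                 "glucose"]
        table = growth_table([core_v1, core_v2], [media[n] for n in order])
        row = table.set_index("medium")
        assert row.loc["glucose", "core_v1 (y/n)"] == "y"
        assert row.loc["glucose", "core_v2 (y/n)"] == "n"
        # the GlcN media are marked as lacking an import route
        assert row.loc["glcn", "core_v2 no_route"] == "glcn_e"

    def test_empty_media_list_gives_empty_table(self, core_v2):
        table = growth_table([core_v2], [])
        assert len(table) == 0


class TestEssentiality:
    def test_threonine_is_essential(self, core_v2, media):
        scan = essentiality_scan(core_v2, media["full"])
        assert scan["thr_e"]["essential"]
        assert scan["thr_e"]["mu_without"] <= 1e-6

    def test_either_amino_sugar_suffices(self, core_v2, media):
        scan = essentiality_scan(core_v2, media["full"])
        assert not scan["glcnac_e"]["essential"]
        assert not scan["galnac_e"]["essential"]

    def test_unused_trace_component_not_essential(self, core_v2, media):
        scan = essentiality_scan(core_v2, media["glcnac"])
        assert not scan["h2o_e"]["essential"]
        assert scan["h2o_e"]["mu_without"] == pytest.approx(
            scan["h2o_e"]["mu_base"], rel=1e-9
        )

    def test_scan_undefined_without_base_growth(self, core_v2, media):
        with pytest.raises(InfeasibleError):
            essentiality_scan(core_v2, media["glucose"])


class TestUptakeScan:
    def test_closed_bound_gives_zero(self, chain):
        out = uptake_scan(chain, chain_medium(), "a_e", [0.0])
        assert out == [(0.0, 0.0)]

    def test_linear_regime_on_chain(self, chain):
        out = dict(uptake_scan(chain, chain_medium(), "a_e", [0, 5, 10]))
        assert out[0] == pytest.approx(0.0, abs=1e-9)
        assert out[5] == pytest.approx(5.0, abs=1e-6)
        assert out[10] == pytest.approx(10.0, abs=1e-6)

    def test_saturation_beyond_internal_bottleneck(self, bottleneck):
        medium = chain_medium()
        out = dict(uptake_scan(bottleneck, medium, "a_e", [0, 5, 7, 10]))
        assert out[5] == pytest.approx(5.0, abs=1e-6)
        assert out[7] == pytest.approx(7.0, abs=1e-6)
        assert out[10] == pytest.approx(7.0, abs=1e-6)  # flat past the bottleneck

    def test_negative_bound_rejected(self, chain):
        with pytest.raises(MediumError):
            uptake_scan(chain, chain_medium(), "a_e", [-1.0])

    def test_unknown_sugar_rejected(self, chain):
        with pytest.raises(MediumError):
            uptake_scan(chain, chain_medium(), "b_e", [1.0])

    @given(st.lists(st.floats(0.0, 10.0), min_size=2, max_size=6))
    def test_growth_monotone_in_uptake(self, grid):
        core = make_toy_model(ToyModelSpec())
        from mucimin.pipeline import packaged_media

        medium = packaged_media()["glcnac"]
        out = uptake_scan(core, medium, "glcnac_e", sorted(grid))
        mus = [mu for _, mu in out]
        assert all(b >= a - 1e-6 for a, b in zip(mus, mus[1:]))


class TestFluxComparison:
    def test_deacetylation_lower_on_sugar_mixture(self, core_v2, media):
        df = compare_flux_distributions(
            core_v2, [media["glcnac"], media["glcnac_glucose"]],
            reactions=[DEACETYLASE_ID],
        ).set_index("reaction_id")
        assert df.loc[DEACETYLASE_ID, "glcnac_glucose class"] == "lower"
        assert df.loc[DEACETYLASE_ID, "glcnac class"] == "higher"

    def test_identical_media_all_similar(self, core_v2, media):
        twin = MediumSpec("glcnac_twin", media["glcnac"].components,
                          media["glcnac"].sugar_budget)
        df = compare_flux_distributions(core_v2, [media["glcnac"], twin])
        for col in ("glcnac class", "glcnac_twin class"):
            assert (df[col] == "similar").all()

    def test_zero_flux_everywhere_is_similar(self, core_v2, media):
        df = compare_flux_distributions(
            core_v2, [media["glcnac"], media["galnac"]], reactions=["EX_fru"]
        ).set_index("reaction_id")
        assert df.loc["EX_fru", "glcnac class"] == "similar"
        assert df.loc["EX_fru", "galnac class"] == "similar"


class TestMediumSpec:
    def test_json_roundtrip(self, media, tmp_path):
        p = str(tmp_path / "m.json")
        media["glcnac_glucose"].to_json(p)
        back = MediumSpec.from_json(p)
        assert back == media["glcnac_glucose"]

    def test_limited_uptake_requires_bound(self):
        with pytest.raises(MediumError):
            MediumComponent("thr_e", "limited_uptake")

    def test_unknown_category_rejected(self):
        with pytest.raises(MediumError):
            MediumComponent("x_e", "magic")
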
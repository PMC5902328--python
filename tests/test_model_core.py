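"""Model data structures, I/O round-trips, curation and diffing."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mucimin.model import (
    CurationError,
    CurationStep,
    MetabolicModel,
    Metabolite,
    ModelFormatError,
    ModelValidationError,
    Reaction,
    apply_curation,
    curation_steps_from_json,
    curation_steps_to_json,
    diff_models,
    equation_string,
    models_equal,
    parse_equation,
    read_model,
    stoichiometric_matrix,
    write_model,
)
from mucimin.synth import EPIMERASE_ID, GLMS_ID


def three_reaction_toy() -> MetabolicModel:
    mets = [
        Metabolite("s_e", compartment="extracellular"),
        Metabolite("s_c", compartment="cytosol"),
    ]
    rxns = [
        Reaction("EX_s", {"s_e": -1.0}, lower_bound=-10.0),
        Reaction("T_s", {"s_e": -1.0, "s_c": 1.0}),
        Reaction("BIOMASS", {"s_c": -1.0}),
    ]
    return MetabolicModel(mets, rxns, objective_id="BIOMASS", version_tag="toy")


class TestValidation:
    def test_counts_by_construction(self):
        m = three_reaction_toy()
        assert len(m.reactions) == 3
        assert len(m.metabolites) == 2

    def test_exactly_one_boundary_reaction_is_flagged(self):
        m = three_reaction_toy()
        # the biomass drain touches one metabolite but a cytosolic one,
        # so only the true boundary reaction counts as an exchange
        assert m.exchange_ids() == ["EX_s"]

    def test_dangling_metabolite_reference_rejected(self):
        with pytest.raises(ModelValidationError, match="undeclared"):
            MetabolicModel(
                [Metabolite("a_c")],
                [Reaction("r", {"a_c": -1.0, "ghost": 1.0})],
                objective_id="r",
            )

    def test_duplicate_reaction_ids_rejected(self):
        mets = [Metabolite("a_c")]
        rxns = [Reaction("r", {"a_c": -1.0}), Reaction("r", {"a_c": 1.0})]
        with pytest.raises(ModelValidationError, match="duplicate"):
            MetabolicModel(mets, rxns, objective_id="r")

    def test_missing_objective_rejected(self):
        with pytest.raises(ModelValidationError, match="objective"):
            MetabolicModel(
                [Metabolite("a_c")], [Reaction("r", {"a_c": -1.0})],
                objective_id="nope",
            )

    def test_bounds_order_enforced(self):
        with pytest.raises(ModelValidationError, match="lower_bound"):
            Reaction("r", {"a": -1.0}, lower_bound=5.0, upper_bound=1.0)

    def test_empty_stoichiometry_rejected(self):
        with pytest.raises(ModelValidationError, match="empty"):
            Reaction("r", {})


class TestStoichiometricMatrix:
    def test_signed_coefficients_and_shape(self):
        m = three_reaction_toy()
        S = stoichiometric_matrix(m).toarray()
        assert S.shape == (2, 3)
        rows = {met.id: i for i, met in enumerate(m.metabolites)}
        cols = {r.id: j for j, r in enumerate(m.reactions)}
        assert S[rows["s_e"], cols["EX_s"]] == -1.0
        assert S[rows["s_e"], cols["T_s"]] == -1.0
        assert S[rows["s_c"], cols["T_s"]] == 1.0
        assert S[rows["s_c"], cols["BIOMASS"]] == -1.0

    def test_empty_model_gives_0x0(self):
        empty = MetabolicModel([], [], objective_id="")
        assert stoichiometric_matrix(empty).shape == (0, 0)


class TestRoundtrips:
    @pytest.mark.parametrize("fmt,dest", [("sbml", "m.xml"), ("table", "mtab")])
    def test_read_write_identity(self, fmt, dest, tmp_path, core_v1):
        path = str(tmp_path / dest)
        write_model(core_v1, path, fmt)
        back = read_model(path, fmt)
        assert models_equal(core_v1, back)
        assert back.objective_id == core_v1.objective_id

    def test_refuses_to_write_duplicate_ids(self, tmp_path):
        m = three_reaction_toy()
        m.reactions.append(Reaction("EX_s", {"s_e": 1.0}))  # corrupt in place
        with pytest.raises(ModelValidationError, match="duplicate"):
            write_model(m, str(tmp_path / "bad.xml"), "sbml")

    def test_sbml_parse_error_names_problem(self, tmp_path):
        bad = tmp_path / "bad.xml"
        bad.write_text("<sbml><model><listOfSpecies>")
        with pytest.raises(ModelFormatError):
            read_model(str(bad), "sbml")

    def test_table_missing_sheet_rejected(self, tmp_path):
        (tmp_path / "t").mkdir()
        with pytest.raises(ModelFormatError, match=r"\.tsv"):
            read_model(str(tmp_path / "t"), "table")

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            read_model(str(tmp_path / "x"), "xlsx")


class TestEquationGrammar:
    @pytest.mark.parametrize(
        "stoich,lb",
        [
            ({"a": -2.0, "b": -1.0, "c": 1.0}, 0.0),
            ({"a": -1.0, "b": 3.5}, -1000.0),
            ({"a": -1.0}, 0.0),  # pure drain: empty right-hand side
            ({"a": 0.25, "b": -0.5}, 0.0),
        ],
    )
    def test_render_parse_roundtrip(self, stoich, lb):
        rxn = Reaction("r", stoich, lower_bound=lb, upper_bound=1000.0)
        assert parse_equation(equation_string(rxn)) == pytest.approx(stoich)

    def test_arrow_encodes_reversibility_only(self):
        rev = Reaction("r", {"a": -1.0, "b": 1.0}, lower_bound=-5.0)
        irr = Reaction("r", {"a": -1.0, "b": 1.0})
        assert "<=>" in equation_string(rev)
        assert "-->" in equation_string(irr)

    def test_missing_arrow_rejected(self):
        with pytest.raises(ModelFormatError, match="arrow"):
            parse_equation("a + b")


class TestCuration:
    def test_remove_glms_reproduces_curated_network(self, core_v1, core_v2):
        curated, log = apply_curation(
            core_v1, [CurationStep("remove_reaction", GLMS_ID)]
        )
        assert models_equal(curated, core_v2)
        assert len(log) == 1
        assert core_v1.reaction(GLMS_ID)  # source untouched

    def test_empty_step_list_is_identity(self, core_v1):
        out, log = apply_curation(core_v1, [])
        assert models_equal(out, core_v1)
        assert len(log) == 0

    def test_add_reversible_epimerase(self):
        m = three_reaction_toy()
        epim = Reaction(
            EPIMERASE_ID, {"udp_glcnac_c": -1.0, "udp_galnac_c": 1.0},
            lower_bound=-1000.0,
        )
        step = CurationStep(
            "add_reaction", epim,
            new_metabolites=(
                Metabolite("udp_glcnac_c"), Metabolite("udp_galnac_c"),
            ),
        )
        out, _ = apply_curation(m, [step])
        assert len(out.reactions) == len(m.reactions) + 1
        assert out.reaction(EPIMERASE_ID).reversible

    def test_remove_absent_reaction_rejected(self, core_v2):
        with pytest.raises(CurationError, match="absent"):
            apply_curation(core_v2, [CurationStep("remove_reaction", GLMS_ID)])

    def test_add_duplicate_id_rejected(self, core_v1):
        dup = Reaction(GLMS_ID, {"fru6p_c": -1.0, "glcn6p_c": 1.0})
        with pytest.raises(CurationError, match="duplicate"):
            apply_curation(core_v1, [CurationStep("add_reaction", dup)])

    def test_set_bounds_logged_with_before_after(self, core_v1):
        out, log = apply_curation(
            core_v1, [CurationStep("set_bounds", ("EX_glc", -5.0, 500.0))]
        )
        assert out.reaction("EX_glc").lower_bound == -5.0
        entry = log.entries[0]
        assert entry.before == (0.0, 1000.0)
        assert entry.after == (-5.0, 500.0)

    def test_recipe_json_roundtrip(self, tmp_path):
        steps = [
            CurationStep("remove_reaction", GLMS_ID, rationale="why"),
            CurationStep("set_bounds", ("EX_glc", -5.0, 500.0)),
            CurationStep(
                "add_reaction",
                Reaction("r_new", {"x_c": -1.0}, lower_bound=-2.0),
                new_metabolites=(Metabolite("x_c"),),
            ),
        ]
        path = str(tmp_path / "steps.json")
        curation_steps_to_json(steps, path)
        back = curation_steps_from_json(path)
        assert [s.kind for s in back] == [s.kind for s in steps]
        assert back[0].payload == GLMS_ID
        assert back[1].payload == ("EX_glc", -5.0, 500.0)
        assert back[2].payload.stoichiometry == {"x_c": -1.0}


class TestDiff:
    def test_self_diff_is_empty(self, core_v1):
        assert len(diff_models(core_v1, core_v1)) == 0

    def test_single_removal_detected(self, core_v1, core_v2):
        log = diff_models(core_v1, core_v2)
        assert [s.kind for s in log.steps()] == ["remove_reaction"]
        assert log.steps()[0].payload == GLMS_ID

    def test_replay_reproduces_target(self, core_v1, core_v2):
        log = diff_models(core_v1, core_v2)
        replayed, _ = apply_curation(core_v1, log.steps())
        assert models_equal(replayed, core_v2)


@st.composite
def random_edits(draw):
    """A toy model plus a random edit script applied to it."""
    n_extra = draw(st.integers(0, 3))
    base = three_reaction_toy()
    steps = []
    for i in range(n_extra):
        kind = draw(st.sampled_from(["add", "bounds", "remove_added"]))
        if kind == "add":
            lb = draw(st.sampled_from([0.0, -3.0]))
            steps.append(
                CurationStep(
                    "add_reaction",
                    Reaction(f"extra_{i}", {"s_c": -1.0, f"x{i}_c": 1.0},
                             lower_bound=lb),
                    new_metabolites=(Metabolite(f"x{i}_c"),),
                )
            )
        elif kind == "bounds":
            lb = draw(st.floats(-10, 0))
            steps.append(CurationStep("set_bounds", ("T_s", lb, 1000.0)))
        else:
            steps.append(
                CurationStep(
                    "add_reaction",
                    Reaction(f"tmp_{i}", {"s_c": -1.0}),
                )
            )
            steps.append(CurationStep("remove_reaction", f"tmp_{i}"))
    return base, steps


class TestDiffApplyDuality:
    @given(random_edits())
    def test_apply_diff_recovers_target(self, case):
        base, steps = case
        target, _ = apply_curation(base, steps)
        log = diff_models(base, target)
        rebuilt, _ = apply_curation(base, log.steps())
        assert models_equal(rebuilt, target)
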
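import numpy as np
import pytest
from hypothesis import settings

from mucimin.media import MediumSpec
from mucimin.model import MetabolicModel
from mucimin.pipeline import packaged_media
from mucimin.synth import ToyModelSpec, make_toy_model

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def chain():
    return make_toy_model(ToyModelSpec(kind="chain"))


@pytest.fixture(scope="session")
def parallel():
    return make_toy_model(ToyModelSpec(kind="parallel"))


@pytest.fixture(scope="session")
def bottleneck():
    return make_toy_model(ToyModelSpec(kind="bottleneck"))


@pytest.fixture(scope="session")
def core_v1():
    return make_toy_model(ToyModelSpec(with_glms=True))


@pytest.fixture(scope="session")
def core_v2():
    return make_toy_model(ToyModelSpec(with_glms=False))


@pytest.fixture(scope="session")
def core_v2_glcn():
    return make_toy_model(
        ToyModelSpec(with_glms=False, with_glcn_transporter=True)
    )


@pytest.fixture(scope="session")
def media() -> dict[str, MediumSpec]:
    return packaged_media()


def to_cobra(model: MetabolicModel):
    """Independent dense re-encoding of a model in cobrapy (GLPK solver)."""
    import cobra

    cm = cobra.Model(model.version_tag or "m")
    cm.solver = "glpk"
    mets = {m.id: cobra.Metabolite(m.id, compartment="c") for m in model.metabolites}
    for r in model.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cm.add_reactions([cr])
        cr.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()})
    cm.objective = model.objective_id
    return cm
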
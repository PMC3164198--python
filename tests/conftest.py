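import numpy as np
import pytest

from idomain.synthetic import TemplateSpec, alpha7_spec, core_spec, make_template


@pytest.fixture(scope="session")
def la_template():
    return make_template(TemplateSpec(state="LA"))


@pytest.fixture(scope="session")
def ha_template():
    return make_template(TemplateSpec(state="HA"))


@pytest.fixture(scope="session")
def ia_template():
    return make_template(TemplateSpec(state="IA"))


@pytest.fixture(scope="session")
def core():
    return core_spec()


@pytest.fixture(scope="session")
def alpha7():
    return alpha7_spec()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
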
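import pytest

from mcuncert.idms import evaluate_idms
from mcuncert.synthetic import table1_fixture


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture(scope="session")
def model():
    def _model(values):
        return evaluate_idms(values, warn_bracket=False)

    return _model
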
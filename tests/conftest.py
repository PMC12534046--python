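import pytest

from spliceratio import load_annotation, make_worked_example


@pytest.fixture(scope="session")
def worked_example_text() -> str:
    return make_worked_example()


@pytest.fixture(scope="session")
def worked_example_ann(worked_example_text):
    return load_annotation(worked_example_text)
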
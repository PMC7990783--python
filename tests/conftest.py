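import logging

import pytest

import metaor


@pytest.fixture(autouse=True)
def _quiet_correction_warnings(caplog):
    # continuity-correction warnings are expected on the builtin corpus;
    # keep test output readable while still letting caplog capture them
    logging.getLogger("metaor.effects").setLevel(logging.ERROR)
    logging.getLogger("metaor.bias").setLevel(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def builtin():
    return metaor.builtin_corpus()


@pytest.fixture()
def builtin_effects(builtin):
    return metaor.compute_effects(builtin)
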
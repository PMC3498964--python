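import pytest

from npsim.executive import build_paradigm, theory_preset
from npsim.params import voicekey_profile, word_picture_profile


@pytest.fixture(scope="session")
def voicekey():
    return build_paradigm("voicekey")


@pytest.fixture(scope="session")
def word_picture():
    return build_paradigm("word_picture")


@pytest.fixture
def vk_params():
    return voicekey_profile()


@pytest.fixture
def wp_params():
    return word_picture_profile()


@pytest.fixture
def er_weights():
    return theory_preset("episodic_retrieval")
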
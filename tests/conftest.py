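import pytest

from rasclass import default_knowledge_base, default_transcript_meta


@pytest.fixture(scope="session")
def kb():
    return default_knowledge_base()


@pytest.fixture(scope="session")
def transcript_meta():
    return default_transcript_meta()
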
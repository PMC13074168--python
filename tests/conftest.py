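from __future__ import annotations

import pytest

from deprx import load_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()
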
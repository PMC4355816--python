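import random

import pytest

from tandemhash import DNA, PROTEIN


def random_word(rng: random.Random, alphabet, length: int) -> str:
    return "".join(rng.choices(alphabet.symbols, k=length))


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240917)


@pytest.fixture(params=["dna", "protein"], ids=["dna", "protein"])
def alphabet(request):
    return DNA if request.param == "dna" else PROTEIN
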
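import numpy as np
import pytest

from spacerscope.repeats import default_repeats
from spacerscope.simulate import instantiate_repeat, random_dna


@pytest.fixture(scope="session")
def consensi():
    return default_repeats()


@pytest.fixture(scope="session")
def cons_by_type(consensi):
    return {c.type_label: c for c in consensi}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_clean_spacer(rng, cons, length=None):
    """Random spacer that cannot be mistaken for repeat contamination."""
    from spacerscope.simulate import _looks_like_repeat_fragment

    n = length or cons.expected_spacer_length
    while True:
        s = random_dna(rng, n)
        if not _looks_like_repeat_fragment(s, cons.sequence):
            return s


def make_read(rng, cons, spacers, repeat=None):
    """Amplicon read: repeat + spacer + ... + repeat (concrete repeat)."""
    rep = repeat or instantiate_repeat(rng, cons.sequence)
    parts = [rep]
    for sp in spacers:
        parts.append(sp)
        parts.append(rep)
    return "".join(parts), rep
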
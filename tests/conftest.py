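import pytest
from hypothesis import settings

from lrrmap.repeat_model import Loopout, RepeatProtein

settings.register_profile("suite", max_examples=50, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def leeix2() -> RepeatProtein:
    """31-repeat receptor with a loopout pseudo-unit between repeats 27 and 28."""
    return RepeatProtein(name="LeEIX2", n_repeats=31, loopout=Loopout(after_repeat=27))


@pytest.fixture(scope="session")
def seq_protein() -> RepeatProtein:
    """Tiny sequenced protein for assembly/FASTA tests."""
    return RepeatProtein(
        name="toy",
        n_repeats=3,
        repeat_seqs=("BB", "CC", "DD"),
        ncap_seq="AA",
        ccap_seq="EE",
        loopout=Loopout(after_repeat=2, seq="XX"),
    )
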
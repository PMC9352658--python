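import numpy as np
import pytest

from tmejkit.locus import ReadLayout
from tmejkit.simulate import SimulationConfig, make_locus


@pytest.fixture(scope="session")
def locus():
    return make_locus(seed=7)


@pytest.fixture(scope="session")
def layout(locus):
    return ReadLayout(primer=locus.primer_fwd)


@pytest.fixture
def clean_config():
    """Error-free simulation at modest depth for exact truth-matching tests."""
    return SimulationConfig(seed=5, n_reads=600, substitution_error_rate=0.0, ambiguity_rate=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_event_case(rng, k=10):
    """One random toy locus + read constructed from a random repair event.

    Returns (read_seq, ref_seq, cut_site, kind) where kind describes the
    construction (event, mutated, unrelated).
    """
    n = int(rng.integers(50, 90))
    ref = "".join(rng.choice(list("ACGT"), size=n))
    c = int(rng.integers(20, n - 20))
    u = rng.random()
    if u < 0.2:
        read = "".join(rng.choice(list("ACGT"), size=int(rng.integers(25, 60))))
        return read, ref, c, "unrelated"
    dl = int(rng.integers(0, min(9, c - k) + 1))
    dr = int(rng.integers(0, min(9, n - c - k) + 1))
    ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(0, 7))))
    read = ref[: c - dl] + ins + ref[c + dr :]
    if u < 0.4:
        chars = list(read)
        for _ in range(int(rng.integers(1, 3))):
            i = int(rng.integers(len(chars)))
            chars[i] = rng.choice([b for b in "ACGT" if b != chars[i]])
        return "".join(chars), ref, c, "mutated"
    return read, ref, c, "event"
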
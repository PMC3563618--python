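import numpy as np
import pytest

from centomir.quantify import MiRNAReference

# Synthetic precursor contexts around real mature sequences. The base
# immediately 3' of the mature is chosen so that the additions exercised in
# tests are non-templated (miR-21: continuation G, so +A/+C/+T are
# non-templated; let-7a: continuation C, so +A/+T/+G are non-templated).
MIR21_MATURE = "TAGCTTATCAGACTGATGTTGA"
LET7A_MATURE = "TGAGGTAGTAGGTTGTATAGTT"


@pytest.fixture(scope="session")
def mir21_ref():
    precursor = "GGACC" + MIR21_MATURE + "G" + "CATTCGTAGACGACCTG"
    return MiRNAReference(name="hsa-miR-21", mature=MIR21_MATURE, precursor=precursor)


@pytest.fixture(scope="session")
def let7a_ref():
    precursor = "TGGGA" + LET7A_MATURE + "C" + "TAGGGTCACACCCACCA"
    return MiRNAReference(name="hsa-let-7a", mature=LET7A_MATURE, precursor=precursor)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
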
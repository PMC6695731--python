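import numpy as np
import pytest

from delsub.design import build_design


@pytest.fixture(scope="session")
def tiny_design():
    """2x2x2x2 doubly encoded design (16 molecules, 32 genes)."""
    return build_design({"n": [2, 2, 2, 2], "codon_seed": 7})


@pytest.fixture(scope="session")
def small_design():
    """3x3x3x2 doubly encoded design (54 molecules, 108 genes)."""
    return build_design({"n": [3, 3, 3, 2], "codon_seed": 5})


@pytest.fixture(scope="session")
def explicit_design():
    """Hand-written codon tables with known pairwise distances (d_min = 8).

    Within every cycle the four codons are mutually at Hamming distance
    >= 8, so mismatch behaviour is fully predictable.
    """
    c = {
        (1, "A"): {0: "A" * 20, 1: "A" * 12 + "C" * 8},
        (1, "B"): {0: "G" * 20, 1: "G" * 12 + "T" * 8},
        (2, "A"): {0: "C" * 20, 1: "C" * 12 + "A" * 8},
        (2, "B"): {0: "T" * 20, 1: "T" * 12 + "G" * 8},
        (3, "A"): {0: "A" * 10 + "G" * 10, 1: "C" * 10 + "T" * 10},
        (3, "B"): {0: "G" * 10 + "A" * 10, 1: "T" * 10 + "C" * 10},
        (4, "shared"): {0: "T" * 20, 1: "T" * 12 + "A" * 8},
    }
    return build_design(
        {
            "n": [2, 2, 2, 2],
            "codon_tables": {f"{cy}/{lin}": ent for (cy, lin), ent in c.items()},
            "common_sequences": ["AC" * 10] * 5,
            "d_min": 8,
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
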
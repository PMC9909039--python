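import numpy as np
import pytest

from bitterpep.peptides import STANDARD_RESIDUES


def random_peptides(n, rng, min_len=2, max_len=30):
    residues = np.array(list(STANDARD_RESIDUES))
    out = []
    for _ in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        out.append("".join(rng.choice(residues, size=length)))
    return out


@pytest.fixture(scope="session")
def seeded_peptides():
    """200 random peptides of lengths 2-30, fixed seed."""
    return random_peptides(200, np.random.default_rng(20230126))
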
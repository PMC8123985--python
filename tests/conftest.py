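import numpy as np
import pytest

from pscpred.io_formats import AA_ALPHABET, CLASSES, Dataset, ProteinRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_aa(rng, length):
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def random_ss(rng, length):
    return "".join(rng.choice(list("HEC"), size=length))


@pytest.fixture
def tiny_dataset(rng):
    records = []
    for i, cls in enumerate(CLASSES):
        for j in range(2):
            n = int(rng.integers(40, 60))
            records.append(
                ProteinRecord(
                    id=f"p{i}{j}",
                    aa_seq=random_aa(rng, n),
                    ss_seq=random_ss(rng, n),
                    label=cls,
                )
            )
    return Dataset(records=records)
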
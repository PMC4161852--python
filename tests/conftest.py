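import logging

import numpy as np
import pytest

from qbgs.mgmt import synthetic_mgmt_reference
from qbgs.reference import ReferenceSequence, enumerate_cpgs
from qbgs.survival import SurvivalTable

logging.getLogger("qbgs").setLevel(logging.ERROR)

# Small amplicon-like reference: a handful of CpGs plus non-CpG cytosines
# (the latter carry the conversion-efficiency signal).
TOY_SEQ = (
    "ATTGACGTTAGGTCATTCGATTGGATCAGGTACGTTAGGACGATTCCATT"
    "AGGTTCGAAGGTTACGGATTCACGGATTA"
)


@pytest.fixture(scope="session")
def toy_ref() -> ReferenceSequence:
    return ReferenceSequence(name="toy_amplicon", sequence=TOY_SEQ)


@pytest.fixture(scope="session")
def toy_map(toy_ref):
    return enumerate_cpgs(toy_ref)


@pytest.fixture(scope="session")
def mgmt_ref() -> ReferenceSequence:
    return synthetic_mgmt_reference()


def random_survival(rng, n, censor=0.3, scale=10.0) -> SurvivalTable:
    """Random untied survival table for oracle comparisons."""
    time = rng.exponential(scale, n)
    event = (rng.random(n) > censor).astype(int)
    if event.sum() == 0:
        event[int(rng.integers(n))] = 1
    return SurvivalTable([f"s{i}" for i in range(n)], time, event)
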
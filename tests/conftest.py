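import numpy as np
import pytest

import mitorecomb as mr


@pytest.fixture(scope="session")
def direct_sim():
    """20 kb circle with one planted exact 300 bp direct repeat."""
    cfg = mr.SimulationConfig(
        seed=11,
        chromosome_lengths=(20_000,),
        repeats=(mr.PlantedRepeat(length=300, orientation="direct"),),
    )
    return mr.simulate_genome(cfg)


@pytest.fixture(scope="session")
def inverted_sim():
    """20 kb circle with one planted exact 300 bp inverted repeat."""
    cfg = mr.SimulationConfig(
        seed=12,
        chromosome_lengths=(20_000,),
        repeats=(mr.PlantedRepeat(length=300, orientation="inverted"),),
    )
    return mr.simulate_genome(cfg)


@pytest.fixture(scope="session")
def inter_sim():
    """Two circles joined by a planted exact 300 bp inter-molecular repeat."""
    cfg = mr.SimulationConfig(
        seed=13,
        chromosome_lengths=(20_000, 12_000),
        repeats=(mr.PlantedRepeat(length=300, orientation="direct", chrom2=1),),
    )
    return mr.simulate_genome(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_dna(rng, n: int, gc: float = 0.45) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
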
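import numpy as np
import pytest

from invadiv.dataio import PopulationMetadata, SequenceRecord
from invadiv.evolution import SubstitutionModel


@pytest.fixture
def jc():
    return SubstitutionModel("JC69")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_records(rng, n=6, length=30, populations=("a", "b")):
    """Random equal-length records split over populations."""
    bases = np.array(list("ACGT"))
    out = []
    for i in range(n):
        seq = "".join(bases[rng.integers(0, 4, size=length)])
        out.append(SequenceRecord(id=f"s{i}", population=populations[i % len(populations)],
                                  sequence=seq))
    return out


def meta_row(population="p1", species="sp", status="invasive",
             distribution="native", region="r1", latitude=54.0,
             longitude=10.0, n=5):
    return PopulationMetadata(population=population, species=species,
                              status=status, distribution=distribution,
                              region=region, latitude=latitude,
                              longitude=longitude, n=n)
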
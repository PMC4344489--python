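"""Shared fixtures: small synthetic genomes and deterministic seeds."""

import numpy as np
import pytest

from linenahr.io_formats import GenomeAssembly, RepeatElement
from linenahr.synthetic import FamilySpec, SimulationConfig, make_genome


@pytest.fixture(scope="session")
def small_family_genome():
    """One 500 kb chromosome with six planted copies at 97% identity."""
    cfg = SimulationConfig(
        seed=11,
        chromosomes={"chr1": 500_000},
        families=[FamilySpec(name="L1T", n_copies=6, length=6000, target_identity=97.0)],
    )
    return make_genome(cfg)


@pytest.fixture()
def toy_genome():
    """A tiny hand-built genome for interval arithmetic tests."""
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), size=100_000))
    return GenomeAssembly(sequences={"chr1": seq})


@pytest.fixture()
def element_factory():
    def make(eid="e1", chrom="chr1", start=1000, end=7000, strand="+", family="L1"):
        return RepeatElement(id=eid, chromosome=chrom, start=start, end=end,
                             strand=strand, family=family)

    return make
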
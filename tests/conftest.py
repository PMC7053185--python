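import numpy as np
import pytest
from hypothesis import settings

from methylhet import synthetic_data as sd
from methylhet.epiread_core import EpiRead

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture
def tiny_config():
    return sd.SimulationConfig(n_loci=10, cpg_spacing=10, locus_spacing=50, seed=42)


@pytest.fixture
def tiny_reference(tiny_config):
    return sd.simulate_reference(tiny_config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_reads(pattern_counts, contig="chrS", first_cpg_index=0, prefix="r"):
    """Whole-locus reads realizing given {pattern: count} at one locus."""
    reads = []
    i = 0
    for pattern, count in pattern_counts.items():
        for _ in range(count):
            reads.append(
                EpiRead(
                    read_id=f"{prefix}{i}",
                    contig=contig,
                    first_cpg_index=first_cpg_index,
                    states=pattern,
                )
            )
            i += 1
    return reads
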
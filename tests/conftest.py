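import numpy as np
import pytest

from strainscope.io_formats import FeatureRecord
from strainscope.simulate import SimulationConfig, make_genome


def make_feature(tag, start, end, strand="+", labels=(), ftype="CDS"):
    return FeatureRecord(
        locus_tag=tag,
        feature_type=ftype,
        start=start,
        end=end,
        strand=strand,
        function_labels=frozenset(labels),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def default_sim():
    """Synthetic genome at the study-condition defaults (200 kb, 150 genes,
    5 planted PULs including one double-anchor locus)."""
    return make_genome(SimulationConfig(rng_seed=11))


@pytest.fixture(scope="session")
def small_sim():
    """A lighter genome for per-read alignment tests."""
    config = SimulationConfig(
        rng_seed=5,
        genome_length_bp=60_000,
        n_genes=45,
        n_puls=2,
        n_background_cazy=2,
        n_reads=2_000,
    )
    return make_genome(config)
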
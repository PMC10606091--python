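import numpy as np
import pytest

from driftscan import synthpop
from driftscan.genio import GenotypeMatrix, PopulationPanel, VariantRecord


@pytest.fixture(scope="session")
def sardinia():
    """The 94-sample worked-example study: 13 hom-ref / 54 het / 27 hom-alt."""
    gm, panel = synthpop.simulate_genotype_sample(13, 54, 27)
    return gm, panel


@pytest.fixture(scope="session")
def trio():
    """Neutral three-population divergence at the default study conditions."""
    cfg = synthpop.DivergenceConfig(seed=12345)
    gm, panel = synthpop.simulate_divergence(cfg)
    return gm, panel, cfg


@pytest.fixture
def small_matrix():
    """Hand-built 4-sample x 3-variant matrix with one missing call."""
    variants = [
        VariantRecord("chr20", 100, "v1", "A", "G"),
        VariantRecord("chr20", 200, "v2", "C", "T"),
        VariantRecord("chr20", 300, "v3", "G", "A"),
    ]
    dosage = np.array(
        [
            [0, 1, 2],
            [1, 0, 2],
            [2, -1, 2],
            [0, 1, 2],
        ],
        dtype=np.int16,
    )
    samples = ["S1", "S2", "S3", "S4"]
    panel = PopulationPanel(
        entries={
            "S1": ("POPA", "SUP1"),
            "S2": ("POPA", "SUP1"),
            "S3": ("POPB", "SUP1"),
            "S4": ("POPB", "SUP1"),
        }
    )
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage), panel
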
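import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from epimaf.genome import GenomeModel
from epimaf.synth import SyntheticScenario, gen_genome, gen_peaks

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def tiny_genome():
    """Two chromosomes, four genes with hand-placed TSSs.

    chr1: geneA + [10_000, 20_000) tss 10_000
          geneB - [50_000, 60_000) tss 59_999
    chr2: geneC + [100_000, 130_000) tss 100_000
          geneD + [100_000, 140_000) tss 100_000  (tied TSS with geneC)
    """
    genes = pd.DataFrame({
        "gene_id": ["geneA", "geneB", "geneC", "geneD"],
        "chrom": ["chr1", "chr1", "chr2", "chr2"],
        "start": [10_000, 50_000, 100_000, 100_000],
        "end": [20_000, 60_000, 130_000, 140_000],
        "strand": ["+", "-", "+", "+"],
    })
    return GenomeModel(chrom_sizes={"chr1": 1_000_000, "chr2": 1_000_000},
                       genes=genes)


@pytest.fixture(scope="session")
def scenario1():
    return SyntheticScenario(seed=1)


@pytest.fixture(scope="session")
def genome1(scenario1):
    return gen_genome(scenario1)


@pytest.fixture(scope="session")
def peaks1(scenario1, genome1):
    """(peaks, counts, design, truth) for the default scenario, built once."""
    return gen_peaks(scenario1, genome1)


def peak_frame(rows, ids=None):
    """Helper: build a peak DataFrame from (chrom, start, end) rows."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    if ids is not None:
        df.index = ids
    return df
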
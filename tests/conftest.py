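import numpy as np
import pandas as pd
import pytest

from cnvpipe.core import ProbeSet
from cnvpipe.synthetic import GenomeSpec, NoiseSpec, make_probe_grid


@pytest.fixture(scope="session")
def small_genome() -> GenomeSpec:
    return GenomeSpec((("chr1", 10_000_000),), 1000, 400)


@pytest.fixture(scope="session")
def small_probes(small_genome) -> ProbeSet:
    return make_probe_grid(small_genome, seed=7)


@pytest.fixture()
def quiet_noise() -> NoiseSpec:
    return NoiseSpec(log2_sd=0.0, snp_genotype_error=0.0, het_rate=0.3, seed=11)


@pytest.fixture(scope="session")
def cytobands() -> pd.DataFrame:
    """Synthetic hg19-like cytoband table (1-based, as read_cytobands
    returns) covering the regions exercised in formatting tests."""
    rows = [
        # chrom, start, end, name, stain
        ("10", 100_000_001, 101_900_000, "q24.2", "gneg"),
        ("10", 101_900_001, 102_100_000, "q24.31", "gpos50"),
        ("10", 102_100_001, 103_000_000, "q24.32", "gneg"),
        ("17", 57_000_001, 59_500_000, "q23.1", "gneg"),
        ("17", 59_500_001, 60_200_000, "q23.2", "gpos75"),
        ("17", 60_200_001, 62_100_000, "q23.3", "gneg"),
        ("17", 62_100_001, 64_200_000, "q24.1", "gpos25"),
        ("17", 64_200_001, 66_000_000, "q24.2", "gneg"),
        ("chr1", 1, 5_000_000, "p36.33", "gneg"),
        ("chr1", 5_000_001, 10_000_000, "p36.32", "gpos25"),
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "stain"])
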
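import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from offtarget_cnv.config import AnalysisConfig
from offtarget_cnv.coverage import annotate_gc_simulated, build_bins
from offtarget_cnv.genome import GenomicInterval

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def toy_genome():
    """Two small chromosomes reusing hg19 names so arm lookups still work."""
    return {"chr1": 2_000_000, "chr2": 1_500_000}


@pytest.fixture
def toy_panel():
    return [
        (GenomicInterval("chr1", 500_000, 500_500), "GENE_A"),
        (GenomicInterval("chr1", 1_200_000, 1_200_400), "GENE_B"),
        (GenomicInterval("chr2", 700_000, 700_300), "GENE_C"),
    ]


@pytest.fixture
def toy_bins(toy_genome, toy_panel, rng):
    cfg = AnalysisConfig(antitarget_avg_size=50_000, antitarget_margin=5_000)
    bins = build_bins(toy_genome, toy_panel, cfg)
    return annotate_gc_simulated(bins, rng)


def flat_profile_frame(n=400, chrom="chr1", bin_size=100_000, log2=None, weight=None):
    """A synthetic .cnr-like frame on one chromosome."""
    starts = bin_size * np.arange(n)
    return pd.DataFrame(
        {
            "chromosome": chrom,
            "start": starts,
            "end": starts + bin_size,
            "gene": "Antitarget",
            "log2": np.zeros(n) if log2 is None else log2,
            "depth": 1.0,
            "weight": np.ones(n) if weight is None else weight,
        }
    )
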
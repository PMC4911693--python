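import numpy as np
import pandas as pd
import pytest

from embryocirc.ioformats import CountTable, GeneModel, SpikeIn, SpikeInPanel


@pytest.fixture
def plus_gene() -> GeneModel:
    """Five-exon plus-strand gene with 100-nt exons and distinct introns."""
    exons = []
    pos = 1000
    for intron in (0, 500, 700, 900, 1100):
        pos += intron
        exons.append((pos, pos + 100))
        pos += 100
    return GeneModel("gplus", "chr1", "+", tuple(exons))


@pytest.fixture
def minus_gene() -> GeneModel:
    exons = []
    pos = 50_000
    for intron in (0, 400, 600, 800):
        pos += intron
        exons.append((pos, pos + 120))
        pos += 120
    return GeneModel("gminus", "chr1", "-", tuple(exons))


@pytest.fixture
def small_counts() -> CountTable:
    counts = pd.DataFrame(
        {
            "s1": [10, 0, 100],
            "s2": [20, 5, 50],
        },
        index=["gA", "gB", "gC"],
    )
    meta = pd.DataFrame(
        {"total_mapped_reads": [1_000_000, 2_000_000], "read_length": [100, 100]},
        index=["s1", "s2"],
    )
    return CountTable(counts, meta)


@pytest.fixture
def exact_panel() -> SpikeInPanel:
    """ERCC species on an exact line plus the RGC trio."""
    species = [
        SpikeIn(f"E{i}", "ERCC", amt, "attomole", 1000, 20)
        for i, amt in enumerate((0.01, 0.1, 1.0, 10.0))
    ]
    species += [
        SpikeIn("RGC-RFP", "RGC", 1e6, "molecules", 1000, 80),
        SpikeIn("RGC-GFP", "RGC", 1e5, "molecules", 1000, 80),
        SpikeIn("RGC-CRE", "RGC", 1e4, "molecules", 1000, 80),
    ]
    return SpikeInPanel(tuple(species))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
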
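import numpy as np
import pandas as pd
import pytest

from omicweave.omics_io import (
    AnnotationSet,
    GeneAnnotation,
    ProbeManifest,
    SegmentTable,
)
from omicweave.synthetic_data import SimConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """Small coupled dataset shared by fast tests."""
    return simulate(SimConfig(n_samples=80, n_genes=300, seed=42))


@pytest.fixture
def toy_annotation():
    return AnnotationSet(
        [
            GeneAnnotation("gA", "A", "chr1", "+", 10_000, 12_000),
            GeneAnnotation("gB", "B", "chr1", "-", 30_000, 34_000),
            GeneAnnotation("gC", "C", "chr2", "+", 5_000, 9_000, gene_type="lincRNA"),
        ]
    )


@pytest.fixture
def toy_segments():
    return SegmentTable(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s1", "s1", "s2"],
                "chrom": ["chr1", "chr1", "chr2", "chr1"],
                "start": [100, 150, 1000, 9_500],
                "end": [200, 250, 2000, 13_000],
                "n_probes": [10, 10, 20, 8],
                "value": [0.2, 0.4, -0.7, 0.5],
            }
        )
    )


@pytest.fixture
def toy_manifest():
    return ProbeManifest(
        pd.DataFrame(
            {
                "probe_id": ["p1", "p2", "p3", "p4"],
                "chrom": ["chr1", "chr1", "chr1", "chr2"],
                "pos": [8_000, 10_201, 35_500, 5_050],
                "region_class": ["Island", "N_Shore", "S_Shore", "OpenSea"],
                "gene_ids": [["gA"], ["gA"], ["gB"], ["gC"]],
            }
        )
    )


def spearman_bruteforce(x, y):
    """Rank both vectors (average ranks) and take the Pearson correlation —
    an oracle independent of the screening code."""
    xr = pd.Series(x).rank().to_numpy()
    yr = pd.Series(y).rank().to_numpy()
    return float(np.corrcoef(xr, yr)[0, 1])
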
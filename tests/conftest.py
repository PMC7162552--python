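import numpy as np
import pandas as pd
import pytest

from magic.matrix_builder import GeneAnnotation, MagicMatrix, NarrowPeakRecord, TrackMeta


@pytest.fixture
def toy_annotation():
    return [
        GeneAnnotation("GENE1", "chr1", "+", 10_000, 15_000),
        GeneAnnotation("GENE2", "chr1", "-", 40_000, 43_000),
        GeneAnnotation("GENE3", "chr2", "+", 5_000, 9_000),
    ]


@pytest.fixture
def toy_tracks():
    """Two tracks of hand-placed peaks with known per-gene maxima."""
    t1 = [
        NarrowPeakRecord("chr1", 9_500, 9_700, signal_value=3.2),   # GENE1 flank
        NarrowPeakRecord("chr1", 12_000, 12_300, signal_value=7.5),  # GENE1 body
        NarrowPeakRecord("chr1", 41_000, 41_200, signal_value=2.0),  # GENE2 body
    ]
    t2 = [
        NarrowPeakRecord("chr2", 4_500, 5_001, signal_value=9.0),   # 1 bp in GENE3 domain? no: domain starts 4000
        NarrowPeakRecord("chr2", 6_000, 6_100, signal_value=4.0),   # GENE3 body
    ]
    return [
        (TrackMeta("FACA", "cellA"), t1),
        (TrackMeta("FACB", "cellB"), t2),
    ]


@pytest.fixture
def toy_matrix():
    """Hand-built 6-gene x 3-track matrix with simple integer signals."""
    values = pd.DataFrame(
        {
            "FACA_cellA": [0.0, 1.0, 2.0, 5.0, 7.0, 9.0],
            "FACA_cellB": [1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
            "FACB_cellA": [9.0, 7.0, 5.0, 2.0, 1.0, 0.0],
        },
        index=[f"g{i}" for i in range(1, 7)],
    )
    return MagicMatrix(values=values)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
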
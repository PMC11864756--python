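import numpy as np
import pandas as pd
import pytest

from tfinfluence.io import OmicsMatrix, SampleSheet, TFAnnotation


@pytest.fixture
def toy_counts() -> OmicsMatrix:
    values = np.array([
        [100, 300, 5, 40],
        [300, 300, 0, 10],
        [600, 400, 0, 50],
        [0, 0, 0, 0],
    ], dtype=float)
    return OmicsMatrix(
        feature_ids=["geneA", "geneB", "geneC", "geneD"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=values,
        modality="transcript",
    )


@pytest.fixture
def toy_proteins() -> OmicsMatrix:
    values = np.array([
        [1.0, 10.0, 100.0],
        [50.0, 5.0, 0.0],
        [7.0, 7.0, 7.0],
    ])
    return OmicsMatrix(
        feature_ids=["p1", "p2", "p3"],
        sample_ids=["s1", "s2", "s3"],
        values=values,
        modality="protein",
    )


@pytest.fixture
def toy_sheet() -> SampleSheet:
    return SampleSheet(pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "s4"],
        "timepoint": ["estrus", "dpc0.5", "dpc1.5", "dpc2.5"],
        "region": ["IA", "IU", "IA", "IU"],
    }))


@pytest.fixture
def toy_tfs() -> TFAnnotation:
    return TFAnnotation({"geneA", "geneB"})
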
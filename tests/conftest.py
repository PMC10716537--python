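import numpy as np
import pandas as pd
import pytest

from crsig.io import CountMatrix, SampleTable


@pytest.fixture
def tiny_counts() -> CountMatrix:
    return CountMatrix(
        ["g1", "g2", "g3"],
        ["s1", "s2", "s3", "s4"],
        np.array([[3, 0, 10, 7], [5, 5, 5, 5], [0, 1, 2, 3]]),
    )


@pytest.fixture
def tiny_samples() -> SampleTable:
    df = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "treatment": ["control", "control", "CR", "CR"],
            "tissue": ["hypothalamus", "amygdala", "hypothalamus", "amygdala"],
            "duration": ["short", "short", "short", "short"],
        }
    ).set_index("sample_id")
    return SampleTable(df)


@pytest.fixture
def write_tsv(tmp_path):
    def _write(name: str, text: str):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
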
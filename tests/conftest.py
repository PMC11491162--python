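import numpy as np
import pandas as pd
import pytest

from multiroi.data_model import PointPattern, Window


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_cells_csv(tmp_path):
    """3-row toy cell table: one sample, one ROI, no window metadata."""
    path = tmp_path / "cells.csv"
    pd.DataFrame(
        {
            "sample_id": ["s1", "s1", "s1"],
            "roi_id": ["r1", "r1", "r1"],
            "x": [1.0, 2.0, 3.0],
            "y": [1.0, 5.0, 2.0],
            "phenotype": ["tumor", "immune", "tumor"],
        }
    ).to_csv(path, index=False)
    return path


@pytest.fixture
def two_cell_pattern():
    """Two cells at distance 1 in a 10x10 window (the worked K example)."""
    return PointPattern(
        x=np.array([5.0, 5.0]),
        y=np.array([5.0, 6.0]),
        marks=np.array(["a", "a"]),
        window=Window(0, 10, 0, 10),
        sample_id="s",
        roi_id="r",
    )


@pytest.fixture
def ab_pattern():
    """One a-cell and one b-cell at distance 1 in a 10x10 window."""
    return PointPattern(
        x=np.array([5.0, 5.0]),
        y=np.array([5.0, 6.0]),
        marks=np.array(["a", "b"]),
        window=Window(0, 10, 0, 10),
        sample_id="s",
        roi_id="r",
    )


def random_pattern(rng, n=40, width=100.0, height=80.0, marks=("a", "b")):
    return PointPattern(
        x=rng.uniform(0, width, n),
        y=rng.uniform(0, height, n),
        marks=rng.choice(marks, n),
        window=Window(0, width, 0, height),
        sample_id="s",
        roi_id="r",
    )
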
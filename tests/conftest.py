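from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from xenomir.core_tables import CountMatrix, SampleMeta, ScreenConfig
from xenomir.seq_match import MatchConfig


@pytest.fixture
def screen_cfg() -> ScreenConfig:
    return ScreenConfig()


@pytest.fixture
def match_cfg() -> MatchConfig:
    return MatchConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def toy_matrix() -> CountMatrix:
    """Three candidates x four samples, hand-checkable."""
    frame = pd.DataFrame(
        {
            "s1": [1, 0, 5],
            "s2": [2, 0, 5],
            "s3": [3, 0, 5],
            "s4": [4, 0, 5],
        },
        index=["candA", "candZero", "candFlat"],
    )
    return CountMatrix(frame)


@pytest.fixture
def toy_meta() -> list[SampleMeta]:
    return [
        SampleMeta("s1", "lib1", "study1", "plasma"),
        SampleMeta("s2", "lib1", "study1", "plasma"),
        SampleMeta("s3", "lib2", "study1", "cell"),
        SampleMeta("s4", "lib2", "study1", "cell"),
    ]


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
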
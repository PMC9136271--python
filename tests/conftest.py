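import numpy as np
import pandas as pd
import pytest

from selenoscope.datamodel import ExpressionMatrix, GroupDesign
from selenoscope.simulate import SimConfig


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    data = pd.DataFrame(
        {"s1": [3.0, 10.0], "s2": [2.0, 20.0]}, index=["gA", "gB"]
    )
    return ExpressionMatrix(data)


@pytest.fixture
def two_group_design() -> GroupDesign:
    samples = {f"a{i}": "A" for i in range(5)} | {f"b{i}": "B" for i in range(5)}
    return GroupDesign(samples, {"A": 0.0, "B": 1.0}, baseline_group="A")


@pytest.fixture
def small_sim_config() -> SimConfig:
    """Scaled-down five-group design for fast end-to-end tests."""
    return SimConfig(n_genes=300, n_otus=40, n_trend_genes=10, seed=11)


def make_design(n_per_group: int, groups: dict[str, float], baseline: str) -> GroupDesign:
    samples = {
        f"{g}_{k}": g for g in groups for k in range(n_per_group)
    }
    return GroupDesign(samples, groups, baseline)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
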
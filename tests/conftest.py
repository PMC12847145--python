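import numpy as np
import pytest

from stroopgrain.network import (
    LayerSpec,
    NetworkSpec,
    UnitParams,
    WeightBlock,
    default_network,
)


@pytest.fixture(scope="session")
def default_spec() -> NetworkSpec:
    return default_network()


@pytest.fixture(scope="session")
def small_cohort():
    from stroopgrain.synth import CohortConfig, gen_cohort

    return gen_cohort(CohortConfig(n_participants=10, seed=11))


def make_toy_spec(
    n_hidden_bias: float = 0.5,
    weight: float = 1.2,
    tau: float = 0.3,
    gain: float = 1.0,
    lateral: float = -0.5,
) -> NetworkSpec:
    """A hand-checkable full-architecture spec with simple uniform weights."""
    up = lambda g, b, t, n: [UnitParams(g, b, t)] * n
    layers = {
        "color_hidden": LayerSpec(
            "color_hidden", ["red", "green", "neutral"], up(gain, n_hidden_bias, tau, 3), lateral
        ),
        "word_hidden": LayerSpec(
            "word_hidden", ["red", "green", "neutral"], up(gain, n_hidden_bias, tau, 3), lateral
        ),
        "emotion_hidden": LayerSpec(
            "emotion_hidden",
            ["negative", "neutral", "positive"],
            up(gain, n_hidden_bias, tau, 3),
            lateral,
        ),
        "task_control": LayerSpec(
            "task_control",
            ["color_naming", "word_reading", "emotional_processing"],
            up(gain, 0.0, tau, 3),
            lateral,
        ),
        "response": LayerSpec(
            "response", ["red", "green"], up(gain, n_hidden_bias, tau, 2), lateral
        ),
    }
    eye32 = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
    weights = [
        WeightBlock("color_hidden", "response", weight * eye32),
        WeightBlock("response", "color_hidden", weight * eye32.T),
    ]
    return NetworkSpec(layers=layers, weights=weights)
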
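import numpy as np
import pytest

from popburst import AnalysisConfig, Recording, SpikeTrain


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def tiny_recording():
    """Three neurons and one afferent with hand-placed spikes, duration 10 s."""
    return Recording(
        "tiny", 10.0,
        (
            SpikeTrain("n0", "neuron", np.array([0.5, 1.0, 2.5, 7.0]),
                       depth_label="superficial", condition="naive"),
            SpikeTrain("n1", "neuron", np.array([1.1, 3.0, 8.2]),
                       depth_label="deep", condition="naive"),
            SpikeTrain("n2", "neuron", np.array([0.9, 4.4, 9.9])),
            SpikeTrain("a0", "afferent", np.array([2.0, 6.0])),
        ),
    )


@pytest.fixture
def poisson_population():
    """20 uncoordinated Poisson units at 0.72 Hz, 600 s — a synchrony null."""
    rng = np.random.default_rng(42)
    trains = tuple(
        SpikeTrain(f"n{i:02d}", "neuron",
                   np.sort(rng.uniform(0.0, 600.0, rng.poisson(600 * 0.72))))
        for i in range(20)
    )
    return Recording("poisson-null", 600.0, trains)
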
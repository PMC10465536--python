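import pytest

from rvkit.synth import SimulationConfig, generate_community

#: small but fully featured community used across test modules
TINY = dict(
    n_viruses=8,
    virus_length_range=(6000, 15000),
    n_hosts=4,
    host_length_range=(20000, 40000),
    samples_per_group=4,
    depth_panel_size=3,
)


def tiny_config(seed: int = 11, **overrides) -> SimulationConfig:
    kwargs = {**TINY, **overrides}
    return SimulationConfig(seed=seed, **kwargs)


@pytest.fixture(scope="session")
def tiny_bundle():
    return generate_community(tiny_config())
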
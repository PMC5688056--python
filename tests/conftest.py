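import pytest
from hypothesis import settings

from csccp.fixtures import GeneratorSpec, planted_instance, worked_example_instance

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def example_instance():
    """Three positions, two side chains each; target 96 Da is hit by exactly
    two assignments with products 0.512 and 0.032."""
    return worked_example_instance()


def planted_corpus(n_seeds, max_decimals=4, n_feasible_cycle=(1, 2, 3)):
    """Deterministic stream of planted instances: n in 2..6, K in 2..5,
    decimals in 0..max_decimals."""
    for seed in range(n_seeds):
        spec = GeneratorSpec(
            seed=seed,
            n=2 + seed % 5,
            K=2 + seed % 4,
            decimals=seed % (max_decimals + 1),
        )
        instance, planted = planted_instance(
            spec, n_feasible=n_feasible_cycle[seed % len(n_feasible_cycle)]
        )
        yield seed, spec, instance, planted
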
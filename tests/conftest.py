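import pytest
from hypothesis import HealthCheck, settings

import tempoflow as tf

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def tiny_net():
    """A -> B -> C chain with perfectly reliable edges."""
    net = tf.InteractionNetwork()
    net.add(tf.Interaction("A", "B", tf.Directionality.UNIDIRECTIONAL, 1.0))
    net.add(tf.Interaction("B", "C", tf.Directionality.UNIDIRECTIONAL, 1.0))
    return net


@pytest.fixture()
def tiny_part():
    return tf.GeneGroupPartition(early={"A": 2.0}, intermediate={"B": 1.0},
                                 late={"C": 1.0})


@pytest.fixture()
def tiny_params():
    return tf.LPParameters(gamma1=1.0, gamma2=0.5)


@pytest.fixture()
def tiny_result(tiny_net, tiny_part, tiny_params):
    return tf.run_on_data(tiny_net, tiny_part, tiny_params)


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale planted instance used by most integration-level tests."""
    return tf.SyntheticSpec(n_genes=60, n_paths=4, path_len=2,
                            background_edges=150, seed=11)


@pytest.fixture(scope="session")
def small_instance(small_spec):
    return tf.generate_planted_network(small_spec)


@pytest.fixture(scope="session")
def small_result(small_instance):
    net, part, truth = small_instance
    return tf.run_on_data(net, part, tf.LPParameters(gamma1=1.0, gamma2=1.0))
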
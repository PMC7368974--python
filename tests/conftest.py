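import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def triangle():
    return nx.Graph([(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def path3():
    """Path a - b - c."""
    return nx.Graph([("a", "b"), ("b", "c")])


@pytest.fixture
def star4():
    """Star: center 'c' with three leaves."""
    return nx.Graph([("c", "l1"), ("c", "l2"), ("c", "l3")])


def random_connected_gnp(n: int, p: float, seed: int) -> nx.Graph:
    """Connected Erdős–Rényi sample (deterministic retry on the seed)."""
    for attempt in range(50):
        g = nx.gnp_random_graph(n, p, seed=seed + 1000 * attempt)
        if n == 0 or nx.is_connected(g):
            return g
    raise RuntimeError(f"no connected G({n}, {p}) found from seed {seed}")
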
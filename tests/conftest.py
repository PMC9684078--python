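import numpy as np
import pytest

from clonescape.trees import CloneNode, CloneTree


def make_random_tree(n_tips: int, rng, min_len: int = 5,
                     max_len: int = 50) -> CloneTree:
    """Random bifurcating tree with integer (mutation-count) edge lengths."""
    nodes = [CloneNode(name=f"s{i}",
                       length=float(rng.integers(min_len, max_len)))
             for i in range(n_tips)]
    while len(nodes) > 1:
        a = nodes.pop(rng.integers(len(nodes)))
        b = nodes.pop(rng.integers(len(nodes)))
        parent = CloneNode(length=float(rng.integers(min_len, max_len)))
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    root = CloneNode()
    root.add_child(nodes[0])
    return CloneTree(root)


def make_star(labels, length: float = 1.0) -> CloneTree:
    root = CloneNode()
    for i, lab in enumerate(labels):
        root.add_child(CloneNode(name=f"t{i}", length=length, label=lab))
    return CloneTree(root)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """One 500-gland neutral simulation shared across tests."""
    from clonescape.spatial_sim import SimParams, run_to_size

    return run_to_size(SimParams(N_end=500, m=1e-8, genome_size=3e9,
                                 D=1.0, d_push=2, seed=99))
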
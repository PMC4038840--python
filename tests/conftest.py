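import numpy as np
import pytest

from arbormetry import NeuronReconstruction


@pytest.fixture
def y_arbor() -> NeuronReconstruction:
    """Soma root with an axon trunk splitting into two branches; the
    three axon edges are each exactly 1 µm."""
    return NeuronReconstruction(
        ids=[1, 2, 3, 4],
        type_codes=[1, 2, 2, 2],
        xyz=np.array(
            [
                [0.0, 0.0, 0.0],
                [0.0, 0.0, 1.0],
                [0.0, 0.8, 1.6],
                [0.0, -0.8, 1.6],
            ]
        ),
        radius=[15.0, 0.15, 0.15, 0.15],
        parent_ids=[-1, 1, 2, 2],
    )


@pytest.fixture
def straight_axon():
    """Factory for an unbranched axon running along one axis."""

    def make(length_um=900.0, n_nodes=10, axis=0, start=0.0):
        xyz = np.zeros((n_nodes, 3))
        xyz[:, axis] = start + np.linspace(0.0, length_um, n_nodes)
        return NeuronReconstruction(
            ids=np.arange(1, n_nodes + 1),
            type_codes=[1] + [2] * (n_nodes - 1),
            xyz=xyz,
            radius=np.full(n_nodes, 0.15),
            parent_ids=[-1] + list(range(1, n_nodes)),
        )

    return make


def random_tree(seed: int, n_nodes: int = 60, scale: float = 500.0):
    """Small random tree used by conservation/recount tests: node k's
    parent is drawn uniformly among earlier nodes."""
    rng = np.random.default_rng(seed)
    xyz = rng.uniform(0.0, scale, size=(n_nodes, 3))
    parents = [-1] + [int(rng.integers(0, k)) + 1 for k in range(1, n_nodes)]
    return NeuronReconstruction(
        ids=np.arange(1, n_nodes + 1),
        type_codes=[1] + [2] * (n_nodes - 1),
        xyz=xyz,
        radius=np.full(n_nodes, 0.15),
        parent_ids=parents,
    )
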
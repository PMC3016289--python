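import numpy as np
import pytest

from mthaplo.simulate import DemographicModel, MutationModel
from mthaplo.tree import MutationTree, Node
from mthaplo.variants import ReferenceSequence, synthetic_reference


@pytest.fixture(scope="session")
def toy_reference() -> ReferenceSequence:
    return synthetic_reference(length=400, seed=7, name="toy")


@pytest.fixture(scope="session")
def constant_demography() -> DemographicModel:
    return DemographicModel(((0.0, 1000.0),), generation_time=25.0)


@pytest.fixture(scope="session")
def hky_model() -> MutationModel:
    return MutationModel(kappa=22.0, gamma_shape=1.0, n_categories=1)


@pytest.fixture()
def calibration_tree() -> MutationTree:
    """Fixed 8-tip topology whose named nodes carry the four calibrations.

    The calibrated clades are mutually well separated in age, so ordering
    constraints essentially never bind and prior-only marginals should
    reproduce the calibration densities.
    """
    root = Node("U5U6split", time=46000.0)
    u6 = Node("u6anc", time=30000.0)
    u5 = Node("u5anc", time=35000.0)
    root.add(u6)
    root.add(u5)
    u6b1 = Node("U6b1", time=3000.0)
    u6.add(u6b1)
    u6.add(Node("t_u6a", time=0.0))
    u6b1.add(Node("t_u6b1_1", time=0.0))
    u6b1.add(Node("t_u6b1_2", time=0.0))
    u5b3a1 = Node("U5b3a1", time=10000.0)
    u5.add(u5b3a1)
    u5.add(Node("t_u5o", time=0.0))
    u5b3a1a = Node("U5b3a1a", time=6000.0)
    u5b3a1.add(u5b3a1a)
    u5b3a1.add(Node("t_u5b3a1_1", time=0.0))
    u5b3a1a.add(Node("t_a1", time=0.0))
    u5b3a1a.add(Node("t_a2", time=0.0))
    tree = MutationTree(root)
    tree.set_lengths_from_times()
    return tree


def random_mutation_tree(rng: np.random.Generator, n_tips: int,
                         mean_muts: float = 1.5) -> MutationTree:
    """Random nested topology with Poisson transition counts per branch."""
    from mthaplo.variants import VariantCall

    pos = [1]

    def muts(k):
        out = []
        for _ in range(k):
            out.append(VariantCall(pos[0], "A", "G"))
            pos[0] += 1
        return out

    nodes = [Node(f"t{i}", mutations=muts(rng.poisson(mean_muts)))
             for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = Node(mutations=muts(rng.poisson(mean_muts)))
        parent.add(b)
        parent.add(a)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    root = nodes[0]
    root.mutations = []
    return MutationTree(root, name="random")
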
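import itertools

import dendropy
import numpy as np
import pytest

from splicepotts.alphabet import PAIRS
from splicepotts.io import DonorEnsemble
from splicepotts.model import PottsModel
from splicepotts.synth import make_random_potts


@pytest.fixture
def zero_model() -> PottsModel:
    return PottsModel(np.zeros((9, 4)), np.zeros((36, 16)))


@pytest.fixture
def random_model() -> PottsModel:
    return make_random_potts(seed=2024, n_couplings=12, field_scale=0.5, coupling_scale=0.5)


@pytest.fixture
def tiny_ensemble() -> DonorEnsemble:
    return DonorEnsemble(["CAGGTAAGT"] * 10)


def brute_force_logits(h: np.ndarray, J: np.ndarray) -> np.ndarray:
    """Independent enumeration of -E(S) over all states, lexicographic order."""
    states = np.array(list(itertools.product(range(4), repeat=9)), dtype=np.int64)
    e = h[np.arange(9), states].sum(axis=1)
    for p, (i, j) in enumerate(PAIRS):
        e = e + J[p, states[:, i] * 4 + states[:, j]]
    return e


def brute_force_parsimony(tree: dendropy.Tree, tip_states: dict[str, int]) -> int:
    """Minimum unit-cost changes over all ancestral assignments (exhaustive)."""
    nodes = list(tree.postorder_node_iter())
    internal = [nd for nd in nodes if not nd.is_leaf()]
    best = None
    for assign in itertools.product((0, 1), repeat=len(internal)):
        state = {}
        for nd, s in zip(internal, assign):
            state[id(nd)] = s
        for nd in nodes:
            if nd.is_leaf():
                state[id(nd)] = tip_states[nd.taxon.label]
        changes = 0
        for nd in nodes:
            for ch in nd.child_nodes():
                changes += state[id(nd)] != state[id(ch)]
        if best is None or changes < best:
            best = changes
    return best


def fitch_steps(tree: dendropy.Tree, tip_states: dict[str, int]) -> int:
    """Fitch change counting (independent of the Sankoff DP); binary trees."""
    steps = 0

    def visit(nd):
        nonlocal steps
        if nd.is_leaf():
            return {tip_states[nd.taxon.label]}
        sets = [visit(ch) for ch in nd.child_nodes()]
        inter = set.intersection(*sets)
        if inter:
            return inter
        steps += len(sets) - 1  # binary: one change per empty intersection
        return set.union(*sets)

    visit(tree.seed_node)
    return steps


def random_binary_tree_newick(n_leaves: int, rng: np.random.Generator) -> str:
    nodes = [f"L{k}" for k in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]}:1,{nodes[j]}:1)"
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [merged]
    return nodes[0] + ";"
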
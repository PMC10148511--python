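import itertools
import math

import numpy as np
import pytest

from stoneoak.phylo import STATE_CODES, Phylogeny
from stoneoak.pipeline import load_fixtures
from stoneoak.synthetic import StudyConfig, generate_study


@pytest.fixture(scope="session")
def table1():
    return load_fixtures("table1")


@pytest.fixture(scope="session")
def table3():
    return load_fixtures("table3")


@pytest.fixture(scope="session")
def demo_tree():
    return load_fixtures("demo_tree")


@pytest.fixture(scope="session")
def default_study():
    # seed chosen so both fruit types are represented, as in the real study
    return generate_study(StudyConfig(seed=3))


# ---------------------------------------------------------------------------
# independent oracles

def brute_force_loglik(phy: Phylogeny, tip_states, model) -> float:
    """Mk likelihood by exhaustive summation over internal-node states."""
    nodes = [nd for nd in phy.tree.preorder_node_iter() if not nd.is_leaf()]
    total = 0.0
    for assign in itertools.product([0, 1], repeat=len(nodes)):
        st = {id(nd): s for nd, s in zip(nodes, assign)}
        p = model.root_prior[st[id(phy.postorder[-1])]]
        for nd in phy.tree.preorder_node_iter():
            for ch in nd.child_nodes():
                a = st[id(nd)]
                b = st[id(ch)] if not ch.is_leaf() else STATE_CODES[tip_states[ch.taxon.label]]
                p *= model.transition_matrix(ch.edge.length or 0.0)[a, b]
        total += p
    return math.log(total) if total > 0 else -math.inf


def brute_force_marginals(phy: Phylogeny, tip_states, model):
    """Per-node marginals by exhaustive summation (<= ~8 internal nodes)."""
    nodes = [nd for nd in phy.tree.preorder_node_iter() if not nd.is_leaf()]
    post = {nd.label: np.zeros(2) for nd in nodes}
    for assign in itertools.product([0, 1], repeat=len(nodes)):
        st = {id(nd): s for nd, s in zip(nodes, assign)}
        p = model.root_prior[st[id(phy.postorder[-1])]]
        for nd in phy.tree.preorder_node_iter():
            for ch in nd.child_nodes():
                a = st[id(nd)]
                b = st[id(ch)] if not ch.is_leaf() else STATE_CODES[tip_states[ch.taxon.label]]
                p *= model.transition_matrix(ch.edge.length or 0.0)[a, b]
        for nd, s in zip(nodes, assign):
            post[nd.label][s] += p
    return {k: v / v.sum() for k, v in post.items()}
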
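import numpy as np
import pytest

from constraintdepth.phylogeny import Phylogeny
from constraintdepth.phylo_core import SubstitutionModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def jc():
    return SubstitutionModel.jukes_cantor()


@pytest.fixture
def hky():
    return SubstitutionModel.hky(3.0, [0.3, 0.2, 0.2, 0.3])


@pytest.fixture
def four_tip_tree():
    return Phylogeny.from_newick(
        "((a:0.1,b:0.2):0.15,(c:0.3,d:0.1):0.05):0;",
        clades={"ab": ["a", "b"], "cd": ["c", "d"]},
    )


@pytest.fixture
def five_tip_tree():
    return Phylogeny.from_newick(
        "(((a:0.1,b:0.2):0.1,c:0.25):0.05,(d:0.3,e:0.15):0.1):0;"
    )


@pytest.fixture(scope="session")
def desk_tree():
    from constraintdepth.synthetic_data import desk_scale_tree

    return desk_scale_tree()


def brute_force_column_loglik(tree, model, column, rho=1.0, clade=None):
    """Independent oracle: sum over all internal-node state assignments.

    Enumerates 4^(n_internal) assignments directly from the joint density;
    shares no code with the pruning implementation.
    """
    import itertools

    from constraintdepth.phylo_core import _branch_scales

    internals = [i for i in range(tree.n_nodes) if i >= tree.n_tips]
    scale = _branch_scales(tree, rho, clade)
    Ps = {i: model.transition_matrix(tree.lengths[i] * scale[i])
          for i in range(tree.n_nodes) if tree.parent[i] >= 0}
    tip_codes = {}
    for name, sym in column.items():
        tip_codes[tree.tip_index[name]] = "ACGT-N".index(sym.upper())

    total = 0.0
    for assignment in itertools.product(range(4), repeat=len(internals)):
        state = dict(zip(internals, assignment))
        p = model.frequencies[state[tree.root]]
        for i in range(tree.n_nodes):
            if tree.parent[i] < 0:
                continue
            parent_state = state[tree.parent[i]]
            if i < tree.n_tips:
                code = tip_codes.get(i, 5)
                if code >= 4:
                    continue  # missing: marginalizes to 1
                p *= Ps[i][parent_state, code]
            else:
                p *= Ps[i][parent_state, state[i]]
        total += p
    return np.log(total)
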
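import numpy as np
import pandas as pd
import pytest

import pcmkit as pk


@pytest.fixture(scope="session")
def three_tip():
    return pk.read_tree("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def two_tip():
    return pk.read_tree("(A:1,B:1);")


@pytest.fixture(scope="session")
def balanced_four():
    return pk.read_tree("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def tree26():
    return pk.simulate_bd_tree(26, seed=7, height=5.0)


@pytest.fixture(scope="session")
def posterior26(tree26):
    return pk.pseudo_posterior(tree26, 20, age_jitter_cv=0.1, nni_prob=0.1, seed=11)


def random_tree(n_tips: int, rng: np.random.Generator) -> pk.PhyloTree:
    """Random coalescent-style tree built by successive pair merges."""
    nodes = [f"t{i}" for i in range(n_tips)]
    newicks = {nm: (nm, 0.0) for nm in nodes}  # name -> (newick, age-before-present)
    active = list(nodes)
    depth = 0.0
    counter = 0
    while len(active) > 1:
        depth += rng.exponential(1.0) / len(active)
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        b = active.pop(j)
        a = active.pop(i)
        (na, ha), (nb, hb) = newicks.pop(a), newicks.pop(b)
        nm = f"({na}:{depth - ha:.10f},{nb}:{depth - hb:.10f})"
        counter += 1
        key = f"internal_{counter}"
        newicks[key] = (nm, depth)
        active.append(key)
    nwk, _ = newicks[active[0]]
    return pk.read_tree(nwk + ";")
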
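import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

# the brute-force oracles live next to the acceptance script
sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "scripts"))

from satrate.simulate import study_tree  # noqa: E402


@pytest.fixture(scope="session")
def fixture_tree():
    return study_tree()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def simulate_bm_tips(tree, rng, sigma=1.0, root=500.0, n_units=1):
    """Plain BM simulation on a tree (constant step variance), for tests."""
    out = {}
    for u in range(n_units):
        x = np.zeros(tree.n_nodes)
        x[tree.root_index()] = root
        for i in range(tree.n_nodes):
            p = tree.parent[i]
            if p >= 0:
                x[i] = x[p] + rng.normal(0.0, sigma * np.sqrt(tree.length[i]))
        out[f"u{u}"] = [x[tree.index(t)] for t in tree.tips]
    return pd.DataFrame(out, index=tree.tips)
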
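import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from elevassembly import OtuTable, read_tree

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def four_tip_tree():
    """Two cherries on a shared spine; patristic d(A,C) = 3."""
    return read_tree("((A:1,B:1):0.5,(C:1,D:1):0.5);")


@pytest.fixture
def small_table():
    return OtuTable(
        pd.DataFrame(
            [[3, 0, 2], [1, 2, 0], [0, 4, 4]],
            index=["s1", "s2", "s3"],
            columns=["A", "B", "C"],
        )
    )


@pytest.fixture
def small_metadata():
    return pd.DataFrame(
        {
            "elevation": [400.0, 800.0, 1200.0],
            "pH": [5.0, 4.5, 4.0],
            "latitude": [44.0, 44.01, 44.02],
            "longitude": [-73.9, -73.9, -73.9],
        },
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )


def random_tree(rng: np.random.Generator, n_tips: int):
    """Random coalescent-style tree built by repeated joining (oracle helper)."""
    from skbio import TreeNode

    nodes = []
    for i in range(n_tips):
        t = TreeNode(name=f"T{i}")
        t.length = float(rng.uniform(0.1, 2.0))
        nodes.append(t)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = TreeNode()
        parent.length = float(rng.uniform(0.1, 2.0))
        parent.extend([nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    root = TreeNode()
    root.extend(nodes)
    return root


def brute_force_patristic(tree):
    """Tip-to-tip distances by explicit root-path summation."""

    def path_to_root(tip):
        path, node = [], tip
        while node.parent is not None:
            path.append(node)
            node = node.parent
        return path

    tips = list(tree.tips())
    out = {}
    for a in tips:
        for b in tips:
            pa = path_to_root(a)
            pb = path_to_root(b)
            sa, sb = set(map(id, pa)), set(map(id, pb))
            d = sum(n.length for n in pa if id(n) not in sb)
            d += sum(n.length for n in pb if id(n) not in sa)
            out[(a.name, b.name)] = d
    return out
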
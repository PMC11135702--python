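"""Shared fixtures and independent oracles for the test suite.

The oracles here (state enumeration for likelihoods/posteriors, dense grid
scan for root placement) are deliberately written as plain loops, independent
of the package's vectorized implementations.
"""

import itertools
import math

import dendropy
import numpy as np
import pytest

from orgatlas.phylotree import (
    label_internal_nodes,
    node_label,
    parse_newick,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rooted_tree(rng, n_tips, min_len=0.05, max_len=2.0):
    """Random binary rooted tree via random sequential joining."""
    labels = [f"t{i}" for i in range(n_tips)]
    nodes = [f"{l}:{rng.uniform(min_len, max_len):.8f}" for l in labels]
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        nodes.append(f"({a},{b}):{rng.uniform(min_len, max_len):.8f}")
    tree = parse_newick(nodes[0] + ";")
    tree.is_rooted = True
    label_internal_nodes(tree)
    return tree, labels


def enum_loglik_posteriors(tree, states, q):
    """Brute-force sum over all joint internal-state assignments (ER model)."""
    nodes = list(tree.preorder_node_iter())
    internal = [nd for nd in nodes if not nd.is_leaf()]
    total = 0.0
    acc = {id(nd): 0.0 for nd in internal}
    for assign in itertools.product([0, 1], repeat=len(internal)):
        amap = dict(zip((id(nd) for nd in internal), assign))
        prob = 0.5  # root prior
        for nd in nodes:
            if nd.parent_node is None:
                continue
            s_parent = amap[id(nd.parent_node)]
            s_child = (
                amap[id(nd)] if not nd.is_leaf() else states[nd.taxon.label]
            )
            t = nd.edge.length or 0.0
            e = math.exp(-2.0 * q * t)
            prob *= 0.5 * (1 + e) if s_parent == s_child else 0.5 * (1 - e)
        total += prob
        for nd in internal:
            if amap[id(nd)]:
                acc[id(nd)] += prob
    posts = {node_label(nd): acc[id(nd)] / total for nd in internal}
    return math.log(total), posts


def grid_mad_oracle(tree, n_grid=10_000):
    """Dense grid scan of the MAD criterion, written independently.

    Returns a list of (head tip frozenset, best rho, best score) per branch of
    the derooted tree, computed from explicit per-pair loops at each grid
    position.
    """
    t = tree.clone(depth=1)
    t.deroot()
    # adjacency with edge lengths
    nodes = list(t.preorder_node_iter())
    adj = {id(nd): [] for nd in nodes}
    for nd in nodes:
        if nd.parent_node is not None:
            w = nd.edge.length or 0.0
            adj[id(nd)].append((nd.parent_node, w))
            adj[id(nd.parent_node)].append((nd, w))
    leaves = [nd for nd in nodes if nd.is_leaf()]

    def dists_from(start):
        out = {id(start): 0.0}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, w in adj[id(u)]:
                if id(v) not in out:
                    out[id(v)] = out[id(u)] + w
                    stack.append(v)
        return out

    leaf_d = {id(lf): dists_from(lf) for lf in leaves}
    results = []
    for nd in nodes:
        if nd.parent_node is None:
            continue
        blen = nd.edge.length or 0.0
        head = set(nd.leaf_iter())
        tail = [lf for lf in leaves if lf not in head]
        head = list(head)
        i_node, j_node = nd.parent_node, nd
        # same-side pair deviations do not depend on rho: compute once
        ss_same = 0.0
        n_pairs = 0
        for side, ref in ((tail, i_node), (head, j_node)):
            for x, y in itertools.combinations(side, 2):
                dxy = leaf_d[id(x)][id(y)]
                danc = (
                    dxy + leaf_d[id(x)][id(ref)] - leaf_d[id(y)][id(ref)]
                ) / 2.0
                ss_same += (2.0 * danc / dxy - 1.0) ** 2
                n_pairs += 1
        cross = [
            (leaf_d[id(b)][id(i_node)], leaf_d[id(b)][id(c)])
            for b in tail
            for c in head
        ]
        n_pairs += len(cross)
        best = (math.inf, 0.0)
        for g in range(n_grid + 1):
            rho = g / n_grid
            ss = ss_same
            for dbi, dbc in cross:
                ss += (2.0 * (dbi + rho * blen) / dbc - 1.0) ** 2
            score = math.sqrt(ss / n_pairs)
            if score < best[0]:
                best = (score, rho)
        results.append(
            (frozenset(node_label(lf) for lf in nd.leaf_iter()), best[1], best[0])
        )
    return results
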
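"""Species-tree utilities: newick I/O, MAD and outgroup rooting, MRCAs.

Trees are :class:`dendropy.Tree` objects throughout; tip labels are species
ids. Rooting operations treat the input as an unrooted metric (they deroot a
copy first), so their results are invariant to how the input happened to be
rooted.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import dendropy
import numpy as np

logger = logging.getLogger(__name__)


class NewickError(ValueError):
    pass


class RootingError(ValueError):
    pass


@dataclass(frozen=True)
class RootPlacement:
    """Root position on a branch of the unrooted tree.

    ``branch_index`` indexes the preorder enumeration of branches of the
    derooted tree; ``rho`` is the relative position along the branch measured
    from the parent-side (tail) node; ``mad_score`` is the root-mean-square
    relative deviation over all tip pairs at that position.
    """

    branch_index: int
    tail_tips: frozenset[str]
    head_tips: frozenset[str]
    rho: float
    mad_score: float


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> dendropy.Tree:
    """Parse a newick string (branch lengths kept; polytomies allowed)."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"malformed newick: {exc}") from exc
    for nd in tree.preorder_node_iter():
        if nd.edge.length is not None and not np.isfinite(nd.edge.length):
            raise NewickError("non-finite branch length")
    return tree


def read_newick(path) -> dendropy.Tree:
    with open(path, encoding="utf-8") as fh:
        return parse_newick(fh.read())


def write_newick(tree: dendropy.Tree, path=None) -> str:
    text = tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
        real_value_format_specifier=".12g",
    )
    if path is not None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
    return text


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def ensure_binary(tree: dendropy.Tree) -> dendropy.Tree:
    """Resolve polytomies in place into zero-length cherries, deterministically.

    Children of a polytomy are combined pairwise in order of their smallest
    descendant tip label; new internal edges get length 0.
    """
    changed = False
    for nd in list(tree.preorder_node_iter()):
        kids = nd.child_nodes()
        if len(kids) <= 2:
            continue
        changed = True
        def min_tip(n):
            return min(lf.taxon.label for lf in n.leaf_iter())
        kids = sorted(kids, key=min_tip)
        while len(kids) > 2:
            a, b = kids[0], kids[1]
            nd.remove_child(a)
            nd.remove_child(b)
            merged = dendropy.Node()
            merged.edge.length = 0.0
            merged.add_child(a)
            merged.add_child(b)
            nd.add_child(merged)
            kids = sorted(nd.child_nodes(), key=min_tip)
    if changed:
        logger.warning("polytomies resolved into zero-length cherries")
    return tree


def label_internal_nodes(tree: dendropy.Tree, prefix: str = "N") -> dendropy.Tree:
    """Give every unlabeled internal node a deterministic preorder label.

    Existing labels are kept; generated names skip any label already in use.
    """
    used = {
        nd.label for nd in tree.preorder_node_iter()
        if not nd.is_leaf() and nd.label
    }
    i = 0
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.label:
            continue
        while f"{prefix}{i}" in used:
            i += 1
        nd.label = f"{prefix}{i}"
        used.add(nd.label)
    return tree


def node_label(nd: dendropy.Node) -> str:
    return nd.taxon.label if nd.is_leaf() else nd.label


def pairwise_tip_distances(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(tree.taxon_namespace)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1 :]:
            d = pdm.patristic_distance(t1, t2)
            out[(t1.label, t2.label)] = d
            out[(t2.label, t1.label)] = d
    return out


# ---------------------------------------------------------------------------
# MAD rooting
# ---------------------------------------------------------------------------

def _deroot_copy(tree: dendropy.Tree) -> dendropy.Tree:
    t = tree.clone(depth=1)
    t.deroot()
    for nd in t.preorder_node_iter():
        if nd.parent_node is not None and nd.edge.length is None:
            nd.edge.length = 0.0
    return t


def _leaf_node_distances(t: dendropy.Tree):
    """Return (leaves, node list, leaf x node distance matrix, leaf x leaf)."""
    nodes = list(t.preorder_node_iter())
    index = {id(nd): k for k, nd in enumerate(nodes)}
    leaves = [nd for nd in nodes if nd.is_leaf()]
    n = len(nodes)
    dist = np.zeros((len(leaves), n))
    # adjacency over the unrooted graph
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for nd in nodes:
        if nd.parent_node is not None:
            i, j = index[id(nd.parent_node)], index[id(nd)]
            w = nd.edge.length or 0.0
            adj[i].append((j, w))
            adj[j].append((i, w))
    for li, leaf in enumerate(leaves):
        start = index[id(leaf)]
        seen = np.zeros(n, dtype=bool)
        stack = [(start, 0.0)]
        seen[start] = True
        while stack:
            u, d = stack.pop()
            dist[li, u] = d
            for v, w in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append((v, d + w))
    leaf_idx = {node_label(lf): k for k, lf in enumerate(leaves)}
    node_col = {id(nd): index[id(nd)] for nd in nodes}
    D = np.zeros((len(leaves), len(leaves)))
    for li, leaf in enumerate(leaves):
        D[li] = dist[:, index[id(leaf)]]
    return nodes, leaves, leaf_idx, node_col, dist, D


def _same_side_sq(D: np.ndarray, dvec: np.ndarray) -> float:
    """Sum of squared deviations over pairs on one side of the candidate branch.

    For tips x,y on the same side, the induced ancestor is the divergence point
    of their paths toward the branch; its distance from x is
    (d(x,y) + d(x,ref) - d(y,ref)) / 2 with ref the branch endpoint on their side.
    """
    if len(dvec) < 2:
        return 0.0
    anc = (D + dvec[:, None] - dvec[None, :]) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.abs(2.0 * anc / D - 1.0)
    iu = np.triu_indices(len(dvec), k=1)
    return float(np.sum(r[iu] ** 2))


def _branch_minima(t: dendropy.Tree) -> list[tuple[RootPlacement, dendropy.Node]]:
    """Per-branch MAD minimum (closed-form quadratic in rho, clamped to [0,1])."""
    if sum(1 for _ in t.leaf_node_iter()) < 3:
        raise RootingError("MAD rooting needs at least 3 tips")
    nodes, leaves, leaf_idx, node_col, dist, D = _leaf_node_distances(t)
    L = len(leaves)
    iu = np.triu_indices(L, k=1)
    if np.any(D[iu] <= 0):
        raise RootingError("zero pairwise tip distance; MAD undefined")
    n_pairs = L * (L - 1) // 2
    all_tips = frozenset(node_label(lf) for lf in leaves)
    leaf_rows = {id(lf): k for k, lf in enumerate(leaves)}
    out: list[tuple[RootPlacement, dendropy.Node]] = []
    branches = [nd for nd in t.preorder_node_iter() if nd.parent_node is not None]
    for bi, nd in enumerate(branches):
        blen = nd.edge.length or 0.0
        head_rows = sorted(leaf_rows[id(lf)] for lf in nd.leaf_iter())
        tail_rows = sorted(set(range(L)) - set(head_rows))
        B = np.asarray(tail_rows, dtype=int)
        C = np.asarray(head_rows, dtype=int)
        dbi = dist[B, node_col[id(nd.parent_node)]]
        Dsub = D[np.ix_(B, C)]
        inv2 = 1.0 / Dsub**2
        if blen > 0:
            rho = float(np.sum((Dsub - 2.0 * dbi[:, None]) * inv2)) / (
                2.0 * blen * np.sum(inv2)
            )
            rho = min(max(rho, 0.0), 1.0)
        else:
            rho = 0.0
        ss = float(np.sum((2.0 * (dbi[:, None] + rho * blen) / Dsub - 1.0) ** 2))
        ss += _same_side_sq(D[np.ix_(B, B)], dbi)
        ss += _same_side_sq(D[np.ix_(C, C)], dist[C, node_col[id(nd)]])
        score = float(np.sqrt(ss / n_pairs))
        head = frozenset(node_label(lf) for lf in nd.leaf_iter())
        out.append(
            (RootPlacement(bi, all_tips - head, head, rho, score), nd)
        )
    return out


def mad_branch_scores(tree: dendropy.Tree) -> list[RootPlacement]:
    """MAD minimum for every branch of the unrooted tree (preorder order)."""
    return [p for p, _ in _branch_minima(_deroot_copy(tree))]


def mad_root(tree: dendropy.Tree) -> tuple[dendropy.Tree, RootPlacement]:
    """Root by minimal ancestral deviation.

    For a candidate root at relative position ``rho`` on a branch, every tip
    pair (b, c) contributes the relative deviation ``|2*d(anc,b)/d(b,c) - 1|``
    of its induced ancestor from the pair midpoint; the branch score is the
    RMS over all pairs at the position minimizing it (closed-form quadratic
    minimum, clamped to the branch). The returned root is the global minimum;
    ties break on smallest (branch index, rho).
    """
    t = _deroot_copy(tree)
    best = None
    best_edge = None
    for placement, nd in _branch_minima(t):
        key = (placement.mad_score, placement.branch_index, placement.rho)
        if best is None or key < (best.mad_score, best.branch_index, best.rho):
            best = placement
            best_edge = nd
    assert best is not None and best_edge is not None
    blen = best_edge.edge.length or 0.0
    t.reroot_at_edge(
        best_edge.edge, length1=best.rho * blen, length2=(1 - best.rho) * blen
    )
    t.is_rooted = True
    return t, best


def mad_score_at(tree: dendropy.Tree, head_tips: Iterable[str], rho: float) -> float:
    """MAD score for an explicit placement (used by the grid-scan oracle)."""
    t = _deroot_copy(tree)
    nodes, leaves, leaf_idx, node_col, dist, D = _leaf_node_distances(t)
    L = len(leaves)
    target = frozenset(head_tips)
    branches = [nd for nd in t.preorder_node_iter() if nd.parent_node is not None]
    leaf_rows = {id(lf): k for k, lf in enumerate(leaves)}
    for nd in branches:
        head = frozenset(node_label(lf) for lf in nd.leaf_iter())
        if head != target:
            continue
        blen = nd.edge.length or 0.0
        head_rows = sorted(leaf_rows[id(lf)] for lf in nd.leaf_iter())
        tail_rows = sorted(set(range(L)) - set(head_rows))
        B = np.asarray(tail_rows, dtype=int)
        C = np.asarray(head_rows, dtype=int)
        dbi = dist[B, node_col[id(nd.parent_node)]]
        Dsub = D[np.ix_(B, C)]
        ss = float(np.sum((2.0 * (dbi[:, None] + rho * blen) / Dsub - 1.0) ** 2))
        ss += _same_side_sq(D[np.ix_(B, B)], dbi)
        ss += _same_side_sq(D[np.ix_(C, C)], dist[C, node_col[id(nd)]])
        return float(np.sqrt(ss / (L * (L - 1) // 2)))
    raise RootingError(f"no branch with head tip set {sorted(target)}")


# ---------------------------------------------------------------------------
# Outgroup rooting and ancestors
# ---------------------------------------------------------------------------

def root_on_outgroup(tree: dendropy.Tree, outgroup_tips: Iterable[str]) -> dendropy.Tree:
    """Root at the midpoint of the branch separating ``outgroup_tips``.

    Errors if the outgroup is not one side of any branch of the unrooted tree.
    """
    og = frozenset(outgroup_tips)
    t = _deroot_copy(tree)
    all_tips = frozenset(node_label(lf) for lf in t.leaf_node_iter())
    if not og or not og < all_tips:
        raise RootingError(
            f"outgroup must be a nonempty proper subset of tips; got {sorted(og)}"
        )
    for nd in t.preorder_node_iter():
        if nd.parent_node is None:
            continue
        head = frozenset(node_label(lf) for lf in nd.leaf_iter())
        if head == og or all_tips - head == og:
            blen = nd.edge.length or 0.0
            t.reroot_at_edge(nd.edge, length1=blen / 2.0, length2=blen / 2.0)
            t.is_rooted = True
            return t
    raise RootingError(
        f"outgroup {sorted(og)} is not monophyletic in the unrooted tree "
        f"(no branch induces that split)"
    )


def resolve_ancestors(
    tree: dendropy.Tree, clade_defs: Mapping[str, Iterable[str]]
) -> dict[str, tuple[dendropy.Node, bool]]:
    """Resolve named ancestors to MRCA nodes on a rooted tree.

    Returns name -> (node, monophyly flag); the flag is True when the MRCA's
    descendant tip set equals the given tip set exactly.
    """
    known = {node_label(lf) for lf in tree.leaf_node_iter()}
    out: dict[str, tuple[dendropy.Node, bool]] = {}
    for name in sorted(clade_defs):
        tips = set(clade_defs[name])
        if not tips:
            raise ValueError(f"ancestor {name!r}: empty tip set")
        unknown = tips - known
        if unknown:
            raise ValueError(f"ancestor {name!r}: unknown tips {sorted(unknown)}")
        if len(tips) == 1:
            (tip,) = tips
            node = next(
                lf for lf in tree.leaf_node_iter() if node_label(lf) == tip
            )
            out[name] = (node, True)
            continue
        node = tree.mrca(taxon_labels=sorted(tips))
        clade = {node_label(lf) for lf in node.leaf_iter()}
        out[name] = (node, clade == tips)
    return out
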
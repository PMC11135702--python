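"""Binary equal-rates Markov (Mk/ER) ancestral state reconstruction.

The model has a single rate ``q`` for both gain (0->1) and loss (1->0); over a
branch of length ``t`` the transition probabilities are

    P(stay) = (1 + exp(-2 q t)) / 2,      P(flip) = (1 - exp(-2 q t)) / 2,

with stationary root prior (1/2, 1/2). Likelihoods use the standard pruning
recursion with per-node rescaling; marginal posteriors at a node are the
normalized product of the partial likelihood of the subtree below it and the
conditional likelihood of the rest of the tree (up/down passes, equivalent to
re-rooting at each node).
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .phylotree import node_label, write_newick

logger = logging.getLogger(__name__)

LOG_HALF = math.log(0.5)


class ConstantCharacterError(ValueError):
    """Raised when ML rate fitting is attempted on an invariant character."""


@dataclass(frozen=True)
class BinaryCharacter:
    """Presence/absence states at the tips of a species tree for one OG."""

    og_id: str
    tip_states: Mapping[str, int]

    def is_constant(self) -> bool:
        vals = set(self.tip_states.values())
        return len(vals) <= 1

    def flipped(self) -> "BinaryCharacter":
        return BinaryCharacter(
            self.og_id, {k: 1 - v for k, v in self.tip_states.items()}
        )


@dataclass(frozen=True)
class GainEventTable:
    """OGs called as newly recruited at each named ancestor."""

    gains: Mapping[str, frozenset[str]]
    threshold: float
    parent_reading: str

    def __getitem__(self, ancestor: str) -> frozenset[str]:
        return self.gains[ancestor]


class PruningEngine:
    """Per-tree cache of traversal order for fast repeated likelihood calls."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.nodes = list(tree.postorder_node_iter())
        self.index = {id(nd): i for i, nd in enumerate(self.nodes)}
        self.n = len(self.nodes)
        self.blen = np.array(
            [nd.edge.length or 0.0 for nd in self.nodes], dtype=float
        )
        self.children = [
            [self.index[id(c)] for c in nd.child_nodes()] for nd in self.nodes
        ]
        self.is_leaf = [nd.is_leaf() for nd in self.nodes]
        self.labels = [node_label(nd) for nd in self.nodes]
        self.leaf_labels = [
            self.labels[i] for i in range(self.n) if self.is_leaf[i]
        ]
        self.root_index = self.index[id(tree.seed_node)]

    # -- internal passes ---------------------------------------------------

    def _tip_vector(self, states: Mapping[str, int]) -> dict[int, int]:
        out = {}
        for i in range(self.n):
            if self.is_leaf[i]:
                lab = self.labels[i]
                s = states.get(lab, 0)
                if s not in (0, 1):
                    raise ValueError(f"tip {lab!r}: state must be 0 or 1, got {s}")
                out[i] = s
        return out

    def _down(self, tips: Mapping[int, int], q: float):
        """Post-order partials F[v][s] with per-node rescaling."""
        e = np.exp(-2.0 * q * self.blen)
        stay = 0.5 * (1.0 + e)
        flip = 0.5 * (1.0 - e)
        F0 = [0.0] * self.n
        F1 = [0.0] * self.n
        logscale = 0.0
        for i in range(self.n):
            if self.is_leaf[i]:
                s = tips[i]
                F0[i] = 1.0 - s
                F1[i] = float(s)
                continue
            f0 = 1.0
            f1 = 1.0
            for c in self.children[i]:
                m0 = stay[c] * F0[c] + flip[c] * F1[c]
                m1 = flip[c] * F0[c] + stay[c] * F1[c]
                f0 *= m0
                f1 *= m1
            m = f0 if f0 >= f1 else f1
            if m <= 0.0:
                return None, None, -math.inf
            F0[i] = f0 / m
            F1[i] = f1 / m
            logscale += math.log(m)
        return F0, F1, logscale

    # -- public API --------------------------------------------------------

    def loglik(self, states: Mapping[str, int], q: float) -> float:
        if q <= 0:
            raise ValueError("rate q must be > 0")
        tips = self._tip_vector(states)
        F0, F1, logscale = self._down(tips, q)
        if F0 is None:
            return -math.inf
        r = self.root_index
        return math.log(0.5 * (F0[r] + F1[r])) + logscale

    def marginals(self, states: Mapping[str, int], q: float) -> dict[str, float]:
        """node label -> P(present); tips report their observed state."""
        if q <= 0:
            raise ValueError("rate q must be > 0")
        tips = self._tip_vector(states)
        F0, F1, _ = self._down(tips, q)
        if F0 is None:
            raise ValueError("zero likelihood; check tip states")
        e = np.exp(-2.0 * q * self.blen)
        stay = 0.5 * (1.0 + e)
        flip = 0.5 * (1.0 - e)
        # G[v][s]: conditional likelihood of everything outside v's subtree
        # given state s at v, including the root prior; normalized per node.
        G0 = [0.0] * self.n
        G1 = [0.0] * self.n
        r = self.root_index
        G0[r] = 0.5
        G1[r] = 0.5
        for i in reversed(range(self.n)):  # pre-order
            if self.is_leaf[i]:
                continue
            kids = self.children[i]
            M0 = []
            M1 = []
            for c in kids:
                M0.append(stay[c] * F0[c] + flip[c] * F1[c])
                M1.append(flip[c] * F0[c] + stay[c] * F1[c])
            for k, c in enumerate(kids):
                s0 = G0[i]
                s1 = G1[i]
                for k2 in range(len(kids)):
                    if k2 == k:
                        continue
                    s0 *= M0[k2]
                    s1 *= M1[k2]
                g0 = s0 * stay[c] + s1 * flip[c]
                g1 = s0 * flip[c] + s1 * stay[c]
                z = g0 + g1
                if z > 0:
                    g0 /= z
                    g1 /= z
                G0[c] = g0
                G1[c] = g1
        out: dict[str, float] = {}
        for i in range(self.n):
            p1 = G1[i] * F1[i]
            p0 = G0[i] * F0[i]
            z = p0 + p1
            out[self.labels[i]] = p1 / z if z > 0 else 0.5
        return out


def loglik(tree: dendropy.Tree, char: BinaryCharacter, q: float) -> float:
    """Log-likelihood of one binary character under the ER model at rate q."""
    return PruningEngine(tree).loglik(char.tip_states, q)


def marginal_posteriors(
    tree: dendropy.Tree, char: BinaryCharacter, q: float
) -> dict[str, float]:
    """Marginal P(present) at every node (tips included, equal to their state)."""
    return PruningEngine(tree).marginals(char.tip_states, q)


def fit_rate(
    tree: dendropy.Tree,
    char: BinaryCharacter,
    bounds: tuple[float, float] = (1e-6, 100.0),
    _engine: PruningEngine | None = None,
) -> tuple[float, float]:
    """Maximum-likelihood rate for one character; returns (q_hat, loglik).

    The search is a coarse log-grid followed by bounded local refinement, so
    the result is deterministic and never worse than the best grid point.
    """
    if char.is_constant():
        raise ConstantCharacterError(
            f"character {char.og_id!r} is constant across tips"
        )
    engine = _engine or PruningEngine(tree)
    states = char.tip_states
    qmin, qmax = bounds
    grid = np.geomspace(qmin, qmax, 40)
    vals = np.array([engine.loglik(states, q) for q in grid])
    k = int(np.argmax(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda lq: -engine.loglik(states, math.exp(lq)),
        bounds=(math.log(lo), math.log(hi)),
        method="bounded",
        options={"xatol": 1e-12},
    )
    q_hat = math.exp(res.x)
    ll_hat = -res.fun
    if vals[k] > ll_hat:
        q_hat, ll_hat = float(grid[k]), float(vals[k])
    return q_hat, ll_hat


def asr_all(
    presence: pd.DataFrame,
    tree: dendropy.Tree,
    rate_bounds: tuple[float, float] = (1e-6, 100.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reconstruct every orthogroup of a presence matrix on a rooted tree.

    Returns ``(posteriors, rates)``: ``posteriors`` has one row per
    (og_id, internal node) with P(present); ``rates`` has per-OG fitted rate,
    log-likelihood and a ``constant`` flag. Constant characters get posterior
    equal to their observed state everywhere and q_hat = 0. Matrix species not
    on the tree are dropped with a warning; tree tips missing from the matrix
    are scored absent.
    """
    engine = PruningEngine(tree)
    tips = set(engine.leaf_labels)
    extra = [c for c in presence.columns if c not in tips]
    if extra:
        logger.warning("dropping %d matrix species not on the tree: %s",
                       len(extra), extra[:5])
    cols = [c for c in presence.columns if c in tips]
    internal = [engine.labels[i] for i in range(engine.n) if not engine.is_leaf[i]]
    post_rows = []
    rate_rows = []
    for og_id in sorted(presence.index):
        row = presence.loc[og_id, cols]
        states = {sp: int(row[sp] > 0) for sp in cols}
        for t in tips - set(cols):
            states[t] = 0
        char = BinaryCharacter(og_id, states)
        if char.is_constant():
            v = float(next(iter(states.values()), 0))
            post = {lab: v for lab in internal}
            rate_rows.append((og_id, 0.0, math.nan, True))
        else:
            q_hat, ll = fit_rate(tree, char, rate_bounds, _engine=engine)
            marg = engine.marginals(states, q_hat)
            post = {lab: marg[lab] for lab in internal}
            rate_rows.append((og_id, q_hat, ll, False))
        for lab in internal:
            post_rows.append((og_id, lab, post[lab]))
    posteriors = pd.DataFrame(post_rows, columns=["og_id", "node", "p_present"])
    rates = pd.DataFrame(
        rate_rows, columns=["og_id", "q_hat", "loglik", "constant"]
    )
    return posteriors, rates


def _pivot(posteriors: pd.DataFrame) -> pd.DataFrame:
    return posteriors.pivot(index="og_id", columns="node", values="p_present")


def call_gains(
    posteriors: pd.DataFrame,
    tree: dendropy.Tree,
    ancestors: Mapping[str, dendropy.Node],
    tau: float,
    parent_reading: str = "confident_absence",
) -> GainEventTable:
    """Call OGs newly recruited at each named ancestor.

    An OG is gained at ancestor A iff P_A(present) > tau (strict) and the
    preceding ancestor is absent: P_parent < 1 - tau under the default
    "confident_absence" reading, or P_parent < tau under the "lax" reading.
    The root has no preceding ancestor and is rejected here (see
    :func:`root_presence`).
    """
    if parent_reading not in ("confident_absence", "lax"):
        raise ValueError(f"unknown parent_reading {parent_reading!r}")
    wide = _pivot(posteriors)
    gains: dict[str, frozenset[str]] = {}
    cut = (1.0 - tau) if parent_reading == "confident_absence" else tau
    for name in sorted(ancestors):
        node = ancestors[name]
        if node.parent_node is None:
            raise ValueError(
                f"ancestor {name!r} is the root; root-state presence is "
                f"reported separately, not as a gain"
            )
        a_lab = node_label(node)
        p_lab = node_label(node.parent_node)
        pa = wide[a_lab]
        pp = wide[p_lab]
        sel = wide.index[(pa > tau) & (pp < cut)]
        gains[name] = frozenset(sel)
    return GainEventTable(gains, tau, parent_reading)


def root_presence(
    posteriors: pd.DataFrame, tree: dendropy.Tree, tau: float
) -> frozenset[str]:
    """OGs confidently present at the root (P > tau); not gain events."""
    wide = _pivot(posteriors)
    root_lab = node_label(tree.seed_node)
    return frozenset(wide.index[wide[root_lab] > tau])


def single_character_report(
    og_id: str, posteriors: pd.DataFrame, tree: dendropy.Tree
) -> tuple[str, pd.DataFrame]:
    """Per-node posterior trace for one OG: annotated newick + tidy table."""
    sub = posteriors[posteriors["og_id"] == og_id]
    if sub.empty:
        raise KeyError(f"orthogroup {og_id!r} not in posterior table")
    pmap = dict(zip(sub["node"], sub["p_present"]))
    t = tree.clone(depth=1)
    for nd in t.preorder_node_iter():
        if not nd.is_leaf():
            lab = node_label(nd)
            if lab in pmap:
                nd.label = f"{lab}_p{pmap[lab]:.6f}"
    table = (
        sub[["node", "p_present"]].sort_values("node").reset_index(drop=True)
    )
    return write_newick(t), table
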
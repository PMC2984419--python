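"""Ancestral reconstruction of the genetic-code state and codon usage.

Two complementary reconstructions formalise the competing evolutionary
scenarios for a patchily distributed non-canonical code:

* **Discrete parsimony** on the binary character standard(0) /
  TAR->Gln(1).  Equal-cost (Fitch) parsimony allows both gains and
  reversals and yields the minimum number of code changes; irreversible
  (Camin-Sokal) parsimony forbids reversals (1->0) and yields the
  minimum number of independent gains.  All maximum-parsimony labelings
  are enumerated exactly (via dynamic programming with backtracking), so
  the gain/loss partition and the event edges are exact, not sampled.

* **Brownian-motion maximum likelihood** for continuous codon-usage
  frequencies.  Under BM the joint-ML ancestral values coincide with the
  GLS / weighted squared-change-parsimony solution: internal values
  minimise sum over edges of (x_child - x_parent)^2 / branch_length.
  The rate sigma^2 is estimated per trait (ML by default, REML
  optionally) and standard errors come from the conditional covariance
  of internal nodes given the tips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .seqio import PhyloTree

__all__ = [
    "DiscreteReconstruction",
    "MPLabeling",
    "fitch_parsimony",
    "camin_sokal_parsimony",
    "BMAncestralEstimate",
    "bm_ancestral_ml",
    "renormalize_simplex",
]

_INF = float("inf")


# ---------------------------------------------------------------------------
# Discrete parsimony
# ---------------------------------------------------------------------------


@dataclass
class MPLabeling:
    """One maximum-parsimony assignment of states to internal nodes.

    Event edges are identified by the tip set of the clade below them
    (stable under node-order changes): ``gains`` lists clades whose stem
    carries a 0->1 change, ``losses`` clades whose stem carries 1->0.
    """

    node_states: dict[frozenset, int]
    gains: list[frozenset]
    losses: list[frozenset]
    root_state: int

    @property
    def n_changes(self) -> int:
        return len(self.gains) + len(self.losses)


@dataclass
class DiscreteReconstruction:
    """Minimum-change reconstruction of a binary character on a rooted tree."""

    tip_states: dict[str, int]
    min_changes: int
    labelings: list[MPLabeling]
    mode: str  # "fitch" | "camin_sokal"

    @property
    def n_mp_labelings(self) -> int:
        return len(self.labelings)

    @property
    def n_gains(self) -> int | None:
        """Gain count, when identical across all MP labelings (else None)."""
        vals = {len(lab.gains) for lab in self.labelings}
        return vals.pop() if len(vals) == 1 else None

    @property
    def n_losses(self) -> int | None:
        vals = {len(lab.losses) for lab in self.labelings}
        return vals.pop() if len(vals) == 1 else None

    @property
    def event_edges(self) -> list[tuple[frozenset, str]]:
        """(clade tip set, 'gain'|'loss') pairs of the unique MP labeling."""
        if len(self.labelings) != 1:
            raise ValueError("event edges are only unambiguous for a unique MP labeling")
        lab = self.labelings[0]
        return [(c, "gain") for c in lab.gains] + [(c, "loss") for c in lab.losses]


def _edge_cost(parent_state: int, child_state: int, irreversible: bool) -> float:
    if parent_state == child_state:
        return 0.0
    if irreversible and parent_state == 1 and child_state == 0:
        return _INF
    return 1.0


def _min_cost_labelings(
    tree: PhyloTree,
    tip_states: Mapping[str, int],
    irreversible: bool,
    root_state: int | None,
    max_labelings: int = 1_000_000,
) -> tuple[float, list[dict]]:
    """Sankoff DP over states {0,1} with full backtracking of optima."""
    root = tree.root
    for leaf in tree.dtree.leaf_node_iter():
        if leaf.taxon.label not in tip_states:
            raise ValueError(f"tip {leaf.taxon.label!r} has no state")
        if tip_states[leaf.taxon.label] not in (0, 1):
            raise ValueError("states must be binary 0/1")

    cost: dict[dendropy.Node, list[float]] = {}
    for node in tree.dtree.postorder_node_iter():
        if node.is_leaf():
            s = tip_states[node.taxon.label]
            cost[node] = [0.0 if s == k else _INF for k in (0, 1)]
        else:
            c = [0.0, 0.0]
            for k in (0, 1):
                for child in node.child_nodes():
                    c[k] += min(
                        _edge_cost(k, j, irreversible) + cost[child][j] for j in (0, 1)
                    )
            cost[node] = c

    if root_state is not None:
        best = cost[root][root_state]
        root_choices = [root_state]
    else:
        best = min(cost[root])
        root_choices = [k for k in (0, 1) if cost[root][k] == best]
    if not math.isfinite(best):
        raise ValueError("no labeling satisfies the constraints")

    # Backtrack every optimal assignment (product over children of their
    # optimal state sets, branching where ties occur).
    labelings: list[dict] = []

    def expand(assignment: dict, frontier: list[dendropy.Node]) -> None:
        if len(labelings) > max_labelings:
            raise RuntimeError("too many maximum-parsimony labelings to enumerate")
        if not frontier:
            labelings.append(dict(assignment))
            return
        node = frontier[0]
        k = assignment[node]
        child_options = []
        for child in node.child_nodes():
            target = min(_edge_cost(k, j, irreversible) + cost[child][j] for j in (0, 1))
            opts = [
                j
                for j in (0, 1)
                if _edge_cost(k, j, irreversible) + cost[child][j] == target
            ]
            child_options.append((child, opts))

        def assign_children(idx: int) -> None:
            if idx == len(child_options):
                rest = frontier[1:] + [
                    ch for ch, _ in child_options if not ch.is_leaf()
                ]
                expand(assignment, rest)
                return
            child, opts = child_options[idx]
            for j in opts:
                assignment[child] = j
                assign_children(idx + 1)
                del assignment[child]

        assign_children(0)

    for k in root_choices:
        expand({root: k}, [root])
    return best, labelings


def _to_mp_labeling(tree: PhyloTree, assignment: dict) -> MPLabeling:
    states: dict[frozenset, int] = {}
    gains: list[frozenset] = []
    losses: list[frozenset] = []
    root = tree.root
    for node, state in assignment.items():
        clade = tree.clade_tips(node)
        states[clade] = state
        parent = node.parent_node
        if parent is not None:
            pstate = assignment[parent]
            if pstate == 0 and state == 1:
                gains.append(clade)
            elif pstate == 1 and state == 0:
                losses.append(clade)
    gains.sort(key=lambda c: (len(c), sorted(c)))
    losses.sort(key=lambda c: (len(c), sorted(c)))
    return MPLabeling(states, gains, losses, assignment[root])


def fitch_parsimony(
    tree: PhyloTree, tip_states: Mapping[str, int]
) -> DiscreteReconstruction:
    """Equal-cost parsimony with every MP labeling enumerated.

    Gains (0->1) and losses (1->0) partition the minimum change count for
    each labeling; a 'single origin + reversal' scenario appears as one
    gain plus one loss.
    """
    best, assignments = _min_cost_labelings(tree, tip_states, False, None)
    labelings = [_to_mp_labeling(tree, a) for a in assignments]
    return DiscreteReconstruction(dict(tip_states), int(best), labelings, "fitch")


def camin_sokal_parsimony(
    tree: PhyloTree, tip_states: Mapping[str, int], ancestral_state: int = 0
) -> DiscreteReconstruction:
    """Irreversible parsimony: losses (1->0) are forbidden.

    With ancestral state 0 the minimum equals the number of maximal
    subtrees whose tips are all in state 1, and the (unique) labeling
    places one gain on each of their stems — the 'independent gains'
    scenario.
    """
    best, assignments = _min_cost_labelings(tree, tip_states, True, ancestral_state)
    labelings = [_to_mp_labeling(tree, a) for a in assignments]
    return DiscreteReconstruction(dict(tip_states), int(best), labelings, "camin_sokal")


# ---------------------------------------------------------------------------
# Brownian-motion ancestral states
# ---------------------------------------------------------------------------


@dataclass
class BMAncestralEstimate:
    """ML ancestral values of continuous traits under Brownian motion.

    ``node_values`` maps each internal node (keyed by its clade tip set)
    to a vector of per-trait estimates; ``sigma2`` holds one BM rate per
    trait in trait-units^2 per unit branch length.
    """

    node_values: dict[frozenset, np.ndarray]
    sigma2: np.ndarray
    root_value: np.ndarray
    standard_errors: dict[frozenset, np.ndarray]
    loglik: np.ndarray
    method: str = "ML"

    def root_clade(self) -> frozenset:
        return max(self.node_values, key=len)


def bm_ancestral_ml(
    tree: PhyloTree,
    tip_values: Mapping[str, Sequence[float] | float],
    method: str = "ML",
) -> BMAncestralEstimate:
    """Joint-ML ancestral reconstruction under univariate Brownian motion.

    Traits are treated independently (one sigma^2 each).  Tips absent
    from ``tip_values`` are pruned first.  Zero-length branches are
    replaced by 1e-8 x tree height to keep the BM covariance invertible.
    ``method`` selects the sigma^2 divisor: ``"ML"`` (n) or ``"REML"``
    (n-1).

    The internal-node solution is the minimiser of
    sum_edges (x_child - x_parent)^2 / t_edge, which equals the GLS /
    empirical-Bayes conditional mean given the tips; on a star tree the
    root is the 1/v-weighted tip mean.
    """
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    have = [t for t in tree.tip_labels if t in tip_values]
    if len(have) < 2:
        raise ValueError("need at least 2 tips with trait values")
    work = tree.prune_to(have) if len(have) < tree.n_tips else tree

    X = np.atleast_2d(
        np.array([np.atleast_1d(np.asarray(tip_values[t], dtype=float)) for t in work.tip_labels])
    )
    n_tips, n_traits = X.shape
    tip_order = work.tip_labels

    eps = 1e-8 * max(work.height(), 1.0)
    nodes = list(work.dtree.preorder_node_iter())
    index = {node: i for i, node in enumerate(nodes)}
    tip_idx = [index[lf] for lf in work.dtree.leaf_node_iter()]
    internal_idx = [i for i, node in enumerate(nodes) if not nodes[i].is_leaf()]
    # map tips back to X rows by label
    label_row = {t: r for r, t in enumerate(tip_order)}

    n_all = len(nodes)
    L = np.zeros((n_all, n_all))
    for node in nodes[1:]:
        t = work.branch_length(node)
        w = 1.0 / max(t, eps)
        i, j = index[node], index[node.parent_node]
        L[i, i] += w
        L[j, j] += w
        L[i, j] -= w
        L[j, i] -= w

    I_ = np.array(internal_idx)
    T_ = np.array(tip_idx)
    L_II = L[np.ix_(I_, I_)]
    L_IT = L[np.ix_(I_, T_)]
    x_tips = np.empty((n_tips, n_traits))
    for node_i, row in zip(tip_idx, range(n_tips)):
        x_tips[row] = X[label_row[nodes[node_i].taxon.label]]

    # internal estimates: L_II x_I = -L_IT x_T  (per trait)
    x_internal = np.linalg.solve(L_II, -L_IT @ x_tips)

    # sigma^2 from the tip marginal: x ~ N(mu 1, sigma^2 C)
    C = _tip_covariance(work, eps)
    Cinv = np.linalg.inv(C)
    ones = np.ones(n_tips)
    denom_mu = ones @ Cinv @ ones
    mu = (ones @ Cinv @ x_tips) / denom_mu
    resid = x_tips - ones[:, None] * mu
    quad = np.einsum("it,ij,jt->t", resid, Cinv, resid)
    dof = n_tips if method == "ML" else n_tips - 1
    sigma2 = quad / dof
    sign, logdet = np.linalg.slogdet(C)
    with np.errstate(divide="ignore"):
        loglik = -0.5 * (
            n_tips * np.log(2 * np.pi * sigma2) + logdet + quad / np.where(sigma2 > 0, sigma2, 1.0)
        )
    loglik = np.where(sigma2 > 0, loglik, np.nan)

    # conditional covariance of internals given tips: sigma^2 * inv(L_II)
    cond = np.linalg.inv(L_II)
    se = np.sqrt(np.clip(np.outer(np.diag(cond), sigma2), 0.0, None))

    node_values: dict[frozenset, np.ndarray] = {}
    standard_errors: dict[frozenset, np.ndarray] = {}
    for k, i in enumerate(internal_idx):
        clade = work.clade_tips(nodes[i])
        node_values[clade] = x_internal[k]
        standard_errors[clade] = se[k]
    root_clade = work.clade_tips(work.root)
    return BMAncestralEstimate(
        node_values=node_values,
        sigma2=sigma2,
        root_value=node_values[root_clade],
        standard_errors=standard_errors,
        loglik=loglik,
        method=method,
    )


def _tip_covariance(tree: PhyloTree, eps: float) -> np.ndarray:
    """BM covariance among tips: shared root-to-MRCA path length."""
    tips = list(tree.dtree.leaf_node_iter())
    depth: dict[dendropy.Node, float] = {tree.root: 0.0}
    for node in tree.dtree.preorder_node_iter():
        if node.parent_node is not None:
            depth[node] = depth[node.parent_node] + max(tree.branch_length(node), eps)
    # ancestors (with depths) per tip
    anc: list[dict[dendropy.Node, float]] = []
    for tip in tips:
        path = {}
        node = tip
        while node is not None:
            path[node] = depth[node]
            node = node.parent_node
        anc.append(path)
    n = len(tips)
    C = np.empty((n, n))
    for i in range(n):
        C[i, i] = depth[tips[i]]
        for j in range(i + 1, n):
            shared = max(
                d for node, d in anc[i].items() if node in anc[j]
            )
            C[i, j] = C[j, i] = shared
    return C


def renormalize_simplex(
    estimates: Mapping[frozenset, np.ndarray] | np.ndarray,
) -> tuple[dict[frozenset, np.ndarray] | np.ndarray, dict[frozenset, np.ndarray] | np.ndarray]:
    """Project per-node trait vectors onto the probability simplex.

    Values are clipped to [0, 1] and renormalised to sum to 1; the raw
    (pre-normalisation) values are returned alongside.  A node whose
    clipped vector is all zero raises, since no direction is defined.
    """
    def _one(v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        clipped = np.clip(v, 0.0, 1.0)
        s = clipped.sum()
        if s == 0:
            raise ValueError("all-zero vector after clipping; cannot renormalise")
        return clipped / s

    if isinstance(estimates, np.ndarray):
        return _one(estimates), estimates.copy()
    out = {k: _one(v) for k, v in estimates.items()}
    raw = {k: np.asarray(v, dtype=float).copy() for k, v in estimates.items()}
    return out, raw
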
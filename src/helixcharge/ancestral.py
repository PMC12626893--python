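"""Maximum-likelihood ancestral states of a continuous trait under Brownian
motion on a rooted phylogeny.

Two independent routes compute the same quantity:

``ancestral_states_fast``
    The re-rooting construction (each internal node's ML state is the
    contrasts root estimate of the tree re-rooted at that node), implemented
    as a two-pass message-passing algorithm: a postorder pruning pass fuses
    tip information toward the root, a preorder pass sends each node the
    information from the rest of the tree, and fusing the two at a node gives
    that node's re-rooted root estimate in overall O(n).

``ancestral_states_gls``
    The brute-force generalized-least-squares oracle on the full phylogenetic
    covariance matrix V (V[i,j] = shared root-to-MRCA path length). Root state
    a0 = (1'V^-1 y)/(1'V^-1 1); internal states from the GLS conditional
    expectation; O(n^3), kept as the validation oracle.

The Brownian rate is the ML estimator sigma2 = (y - a0 1)' V^-1 (y - a0 1)/n
(divide by n, matching the behaviour of the standard fast implementation in
the phylogenetics toolkits). Confidence intervals use the normal
approximation a +/- 1.96 sqrt(Var) with Var scaled by the ML sigma2; the
uncertainty of sigma2 itself is not propagated (documented limitation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .tree import PhyloTree

_CI_Z = 1.959963984540054  # Phi^-1(0.975)
MIN_TERMINAL_BRANCH = 1e-8


@dataclass
class BmFit:
    sigma2_ml: float
    root_state: float
    loglik: float


@dataclass
class AncestralReconstruction:
    """Point estimates, variances and CI95 per internal node, plus the fit."""

    states: dict[str, float]
    variances: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    fit: BmFit
    root_label: str
    tip_order: list[str]

    def as_rows(self) -> list[dict]:
        return [
            {
                "node": node,
                "state": self.states[node],
                "var": self.variances[node],
                "ci_lo": self.ci95[node][0],
                "ci_hi": self.ci95[node][1],
            }
            for node in self.states
        ]


def prepare_tree(
    tree: PhyloTree, traits: Mapping[str, float]
) -> tuple[PhyloTree, dict[str, float], list[str]]:
    """Pair a tree with a tip-trait table for reconstruction.

    Tips without trait values are pruned (reported in the third return
    value); polytomies are resolved to an arbitrary binary form with
    zero-length branches (deterministic, child order as read); zero-length
    terminal branches are floored at 1e-8 so the tip covariance stays
    positive definite.
    """
    tip_set = set(tree.tip_labels)
    with_traits = tip_set & set(traits)
    if len(with_traits) < 2:
        raise ValueError(
            f"need at least 2 trait-bearing tips, found {len(with_traits)}"
        )
    dropped = sorted(tip_set - with_traits)
    pruned = tree.prune_to(with_traits) if dropped else tree.copy()
    resolved = pruned.resolve_polytomies()
    floored = 0
    for tip in resolved.tips():
        if tip.length is not None and tip.length < MIN_TERMINAL_BRANCH:
            tip.length = MIN_TERMINAL_BRANCH
            floored += 1
    if floored:
        warnings.warn(f"floored {floored} zero-length terminal branch(es) at 1e-8")
    used = {t: float(traits[t]) for t in resolved.tip_labels}
    return resolved, used, dropped


def phylo_covariance(tree: PhyloTree) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance matrix among tips.

    V[i, j] is the shared path length from the root to the MRCA of tips i and
    j; the diagonal holds root-to-tip distances. Tip order is the tree's
    postorder tip order (returned alongside).
    """
    tips = tree.tip_labels
    index = {lab: i for i, lab in enumerate(tips)}
    n = len(tips)
    V = np.zeros((n, n))
    depths = tree.depths()
    clade: dict[int, list[int]] = {}
    for node in tree.postorder():
        if node.is_tip:
            i = index[node.label]
            clade[id(node)] = [i]
            V[i, i] = depths[node.label]
        else:
            d = depths[node.label]
            child_clades = [clade[id(c)] for c in node.children]
            for a in range(len(child_clades)):
                for b in range(a + 1, len(child_clades)):
                    for i in child_clades[a]:
                        for j in child_clades[b]:
                            V[i, j] = V[j, i] = d
            clade[id(node)] = [i for cc in child_clades for i in cc]
    return V, tips


def _trait_vector(tree: PhyloTree, traits: Mapping[str, float]) -> np.ndarray:
    missing = [t for t in tree.tip_labels if t not in traits]
    if missing:
        raise KeyError(f"tips without trait values: {missing}")
    return np.array([float(traits[t]) for t in tree.tip_labels])


def ancestral_states_gls(
    tree: PhyloTree, traits: Mapping[str, float]
) -> AncestralReconstruction:
    """GLS oracle: full-matrix ancestral reconstruction, O(n^3)."""
    y = _trait_vector(tree, traits)
    V, tips = phylo_covariance(tree)
    n = len(tips)
    ones = np.ones(n)
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular phylogenetic covariance; floor zero-length terminal "
            "branches (prepare_tree does this)"
        ) from exc
    denom = ones @ Vinv @ ones
    a0 = float(ones @ Vinv @ y / denom)
    resid = y - a0
    sigma2 = float(resid @ Vinv @ resid / n)
    sign, logdet = np.linalg.slogdet(V)
    loglik = -0.5 * n * math.log(2 * math.pi * sigma2) - 0.5 * logdet - 0.5 * n \
        if sigma2 > 0 else math.inf

    depths = tree.depths()
    index = {lab: i for i, lab in enumerate(tips)}

    # c vector per internal node: shared root path with each tip
    states: dict[str, float] = {}
    variances: dict[str, float] = {}
    clade_tips: dict[int, set[str]] = {}
    for node in tree.postorder():
        if node.is_tip:
            clade_tips[id(node)] = {node.label}
        else:
            clade_tips[id(node)] = set().union(
                *(clade_tips[id(c)] for c in node.children)
            )
    for node in tree.internal_nodes():
        c = np.zeros(n)
        inside = clade_tips[id(node)]
        d_node = depths[node.label]
        for t in inside:
            c[index[t]] = d_node
        walker = node
        while walker.parent is not None:
            parent = walker.parent
            above = clade_tips[id(parent)] - clade_tips[id(walker)]
            for t in above:
                c[index[t]] = depths[parent.label]
            walker = parent
        a_hat = a0 + float(c @ Vinv @ resid)
        var = sigma2 * float(
            d_node - c @ Vinv @ c + (1.0 - c @ Vinv @ ones) ** 2 / denom
        )
        var = max(var, 0.0)
        states[node.label] = a_hat
        variances[node.label] = var

    ci = {
        k: (states[k] - _CI_Z * math.sqrt(v), states[k] + _CI_Z * math.sqrt(v))
        for k, v in variances.items()
    }
    return AncestralReconstruction(
        states=states,
        variances=variances,
        ci95=ci,
        fit=BmFit(sigma2_ml=sigma2, root_state=a0, loglik=loglik),
        root_label=tree.root.label,
        tip_order=tips,
    )


def _fuse(messages: list[tuple[float, float]]) -> tuple[float, float, float, float]:
    """Sequentially fuse (mean, variance) messages.

    Returns (fused mean, fused variance, sum of squared standardized
    contrasts, sum of log(v_i + v_j) over fusions) — the latter two accumulate
    the ML quadratic form and log-determinant.
    """
    x, v = messages[0]
    q = 0.0
    logdet = 0.0
    for x2, v2 in messages[1:]:
        q += (x - x2) ** 2 / (v + v2)
        logdet += math.log(v + v2)
        w1, w2 = 1.0 / v, 1.0 / v2
        x = (x * w1 + x2 * w2) / (w1 + w2)
        v = 1.0 / (w1 + w2)
    return x, v, q, logdet


def ancestral_states_fast(
    tree: PhyloTree, traits: Mapping[str, float]
) -> AncestralReconstruction:
    """Two-pass (pruning + redistribution) ancestral reconstruction, O(n).

    Equivalent to re-rooting the tree at every internal node and taking the
    contrasts root estimate there; agrees with :func:`ancestral_states_gls`
    to numerical precision.
    """
    y = {t: float(traits[t]) for t in tree.tip_labels if t in traits}
    missing = set(tree.tip_labels) - set(y)
    if missing:
        raise KeyError(f"tips without trait values: {sorted(missing)}")
    n = tree.n_tips

    # downward pass: message (mean, variance) each subtree sends its parent,
    # measured at the parent (branch length added)
    down: dict[int, tuple[float, float]] = {}
    below: dict[int, tuple[float, float]] = {}  # fused at the node itself
    quad = 0.0
    logdet = 0.0
    for node in tree.postorder():
        if node.is_tip:
            below[id(node)] = (y[node.label], 0.0)
            down[id(node)] = (y[node.label], node.length)
        else:
            msgs = [down[id(c)] for c in node.children]
            x, v, q, ld = _fuse(msgs)
            quad += q
            logdet += ld
            below[id(node)] = (x, v)
            if node.parent is not None:
                if node.length is None:
                    raise ValueError(f"node {node.label!r} lacks a branch length")
                down[id(node)] = (x, v + node.length)

    root = tree.root
    a0, v_root = below[id(root)]
    logdet += math.log(v_root)  # completes log|V|
    sigma2 = quad / n
    loglik = -0.5 * n * math.log(2 * math.pi * sigma2) - 0.5 * logdet - 0.5 * n \
        if sigma2 > 0 else math.inf

    # upward pass: the message each node receives from the rest of the tree
    up: dict[int, tuple[float, float]] = {}
    states: dict[str, float] = {root.label: a0}
    variances: dict[str, float] = {root.label: sigma2 * v_root}
    for node in tree.preorder():
        if node.is_tip:
            continue
        for child in node.children:
            sib_msgs = [down[id(s)] for s in node.children if s is not child]
            if node is not root:
                sib_msgs.append(up[id(node)])
            x, v, _, _ = _fuse(sib_msgs)
            up[id(child)] = (x, v + child.length)
            if not child.is_tip:
                msgs = [down[id(c)] for c in child.children] + [up[id(child)]]
                xs, vs, _, _ = _fuse(msgs)
                states[child.label] = xs
                variances[child.label] = sigma2 * vs

    ci = {
        k: (states[k] - _CI_Z * math.sqrt(v), states[k] + _CI_Z * math.sqrt(v))
        for k, v in variances.items()
    }
    return AncestralReconstruction(
        states=states,
        variances=variances,
        ci95=ci,
        fit=BmFit(sigma2_ml=sigma2, root_state=a0, loglik=loglik),
        root_label=root.label,
        tip_order=list(tree.tip_labels),
    )


def shift_summary(
    recon: AncestralReconstruction, clade_root_label: str
) -> dict[str, float]:
    """Reconstructed state at a clade's stem node versus the tree root."""
    if clade_root_label not in recon.states:
        raise KeyError(f"no reconstructed state for node {clade_root_label!r}")
    root_state = recon.states[recon.root_label]
    clade_state = recon.states[clade_root_label]
    return {
        "root_state": root_state,
        "clade_state": clade_state,
        "delta": clade_state - root_state,
    }
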
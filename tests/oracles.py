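"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own algorithms: likelihoods by
exhaustive enumeration over ancestral assignments, regressions by explicit
normal equations, ranks and distances by direct set arithmetic.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats

from picoevo.gainloss import GainLossModel, branch_transition_probs
from picoevo.model import EvoTree, PhyleticPattern


def enumerate_likelihood(
    model: GainLossModel, tree: EvoTree, leaf_states: dict[str, int]
) -> float:
    """Family likelihood by summing over all 2^n internal-state assignments."""
    nodes = list(tree.preorder())
    internal = [n for n in nodes if not n.is_leaf]
    mats = {
        n.id: branch_transition_probs(model, n.length)
        for n in nodes
        if n.parent is not None
    }
    total = 0.0
    for assign in itertools.product([0, 1], repeat=len(internal)):
        st = {n.id: s for n, s in zip(internal, assign)}
        st.update(leaf_states)
        p = model.pi[st[tree.root.id]]
        for n in nodes:
            if n.parent is not None:
                p *= mats[n.id][st[n.parent.id], st[n.id]]
        total += p
    return total


def enumerate_loglik(
    model: GainLossModel,
    pattern: PhyleticPattern,
    tree: EvoTree,
    condition_observable: bool = True,
) -> float:
    """Total log-likelihood (gamma-mixed, ascertainment-corrected) by enumeration."""
    rates = model.category_rates
    pres = pattern.presence

    def scaled(rate):
        return GainLossModel(
            alpha=model.alpha * rate, beta=model.beta * rate,
            root_prior=model.pi[1] if model.root_prior != "stationary" else "stationary",
        )

    total = 0.0
    p0 = np.mean([
        enumerate_likelihood(scaled(r), tree, {l: 0 for l in tree.leaf_ids})
        for r in rates
    ])
    for j in range(pattern.n_clogs):
        leaf_states = {
            l: int(pres[pattern.strain_index(l), j]) for l in tree.leaf_ids
        }
        lik = np.mean([
            enumerate_likelihood(scaled(r), tree, leaf_states) for r in rates
        ])
        total += np.log(lik)
        if condition_observable:
            total -= np.log1p(-p0)
    return total


def enumerate_marginal(
    model: GainLossModel,
    tree: EvoTree,
    leaf_states: dict[str, int],
    node_id: str,
) -> float:
    """P(node present | leaves) by enumeration, gamma-mixed."""
    rates = model.category_rates
    nodes = list(tree.preorder())
    internal = [n for n in nodes if not n.is_leaf]
    num = den = 0.0
    for rate in rates:
        m = GainLossModel(alpha=model.alpha * rate, beta=model.beta * rate,
                         root_prior=model.root_prior)
        mats = {
            n.id: branch_transition_probs(m, n.length)
            for n in nodes
            if n.parent is not None
        }
        for assign in itertools.product([0, 1], repeat=len(internal)):
            st = {n.id: s for n, s in zip(internal, assign)}
            st.update(leaf_states)
            p = m.pi[st[tree.root.id]]
            for n in nodes:
                if n.parent is not None:
                    p *= mats[n.id][st[n.parent.id], st[n.id]]
            den += p
            if st[node_id] == 1:
                num += p
    return num / den


def random_tree(n_leaves: int, rng: np.random.Generator, unit: str = "subs/site") -> EvoTree:
    """Random rooted binary tree with U(0.05, 1) branch lengths."""
    from picoevo.model import TreeNode

    nodes = [TreeNode(f"L{i}") for i in range(n_leaves)]
    for n in nodes:
        n.label_from_input = True
        n.length = float(rng.uniform(0.05, 1.0))
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = TreeNode("")
        parent.length = float(rng.uniform(0.05, 1.0))
        parent.add_child(nodes.pop(j))
        parent.add_child(nodes.pop(i))
        nodes.append(parent)
    nodes[0].length = 0.0
    return EvoTree(nodes[0], unit)


def origin_regression(x: np.ndarray, y: np.ndarray):
    """Through-origin OLS by explicit normal equations: slope, SE, R2 about 0, p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    slope = float(x @ y / (x @ x))
    resid = y - slope * x
    n = len(x)
    s2 = float(resid @ resid) / (n - 1)
    se = float(np.sqrt(s2 / (x @ x)))
    ss_res = float(resid @ resid)
    ss_tot = float(y @ y)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * n / (n - 1)
    if se == 0:
        p = 0.0 if slope != 0 else 1.0
    else:
        p = 2.0 * stats.t.sf(abs(slope / se), df=n - 1)
    return slope, se, adj_r2, p


def tree_path_length(tree: EvoTree, a: str, b: str) -> float:
    """Patristic distance by explicit per-leaf root paths."""
    def path(leaf):
        node = tree.node(leaf)
        out = []
        while node.parent is not None:
            out.append(node)
            node = node.parent
        return out

    pa, pb = path(a), path(b)
    ia = {n.id for n in pa}
    shared = [n for n in pb if n.id in ia]
    if not shared:
        return sum(n.length for n in pa) + sum(n.length for n in pb)
    mrca = shared[0]
    da = 0.0
    for n in pa:
        if n.id == mrca.id:
            break
        da += n.length
    db = 0.0
    for n in pb:
        if n.id == mrca.id:
            break
        db += n.length
    return da + db
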
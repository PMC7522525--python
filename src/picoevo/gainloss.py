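"""Maximum-likelihood gene gain/loss reconstruction on a fixed rooted tree.

Each gene family evolves independently as a two-state continuous-time Markov
chain on the tree: state 0 = absent, 1 = present, gain rate ``alpha``
(0 -> 1) and loss rate ``beta`` (1 -> 0) per unit branch length.  The
transition matrix over a branch of length t is

    P01(t) = a/(a+b) * (1 - e^{-(a+b)t})      P00(t) = 1 - P01(t)
    P10(t) = b/(a+b) * (1 - e^{-(a+b)t})      P11(t) = 1 - P10(t)

Among-family rate variation is modeled by a K-category discrete-gamma
multiplier (equal prior mass, mean 1) applied jointly to both rates.  The
likelihood is computed by Felsenstein's pruning algorithm and, because
families absent from every genome are unobservable, is conditioned on
presence in at least one tip (ascertainment correction); without this the
gain-rate MLE is biased downward.

Marginal ancestral presence posteriors come from the standard up-down pass;
states are binarized only where max(p, 1-p) reaches the posterior cutoff
(default 90%), and branches touching an ambiguous state contribute no event,
keeping per-branch gain/loss counts conservative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import gamma as gamma_dist

from .model import EvoTree, PhyleticPattern

AMBIGUOUS = -1


@dataclass
class GainLossModel:
    alpha: float                      # gain rate, 0 -> 1, per unit branch length
    beta: float                       # loss rate, 1 -> 0
    k_gamma: int = 1                  # discrete-gamma categories (1 = homogeneous)
    shape: float = 1.0                # gamma shape when k_gamma > 1
    root_prior: str | float = "stationary"  # "stationary" or fixed pi1 in (0,1)

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")
        if self.k_gamma < 1:
            raise ValueError("k_gamma must be >= 1")
        if self.k_gamma > 1 and self.shape <= 0:
            raise ValueError("gamma shape must be > 0")

    @property
    def stationary(self) -> np.ndarray:
        s = self.alpha + self.beta
        return np.array([self.beta / s, self.alpha / s])

    @property
    def pi(self) -> np.ndarray:
        if self.root_prior == "stationary":
            return self.stationary
        pi1 = float(self.root_prior)
        return np.array([1.0 - pi1, pi1])

    @property
    def category_rates(self) -> np.ndarray:
        """Per-category rate multipliers (equal mass, mean exactly 1)."""
        if self.k_gamma == 1:
            return np.array([1.0])
        k = self.k_gamma
        # median of each equal-mass category, renormalized to mean 1
        q = (2.0 * np.arange(k) + 1.0) / (2.0 * k)
        r = gamma_dist.ppf(q, self.shape, scale=1.0 / self.shape)
        return r / r.mean()


def branch_transition_probs(model: GainLossModel, t: float, rate_mult: float = 1.0) -> np.ndarray:
    """2x2 transition matrix over a branch of length ``t`` (rows = start state)."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    a = model.alpha * rate_mult
    b = model.beta * rate_mult
    s = a + b
    e = np.exp(-s * t)
    p01 = a / s * (1.0 - e)
    p10 = b / s * (1.0 - e)
    return np.array([[1.0 - p01, p01], [p10, 1.0 - p10]])


# ---------------------------------------------------------------------------
# Pruning engine
# ---------------------------------------------------------------------------


class _Pruner:
    """Vectorized pruning over all families at once, with per-family scaling."""

    def __init__(self, pattern: PhyleticPattern, tree: EvoTree) -> None:
        leaves = set(tree.leaf_ids)
        missing = leaves - set(pattern.strains)
        if missing:
            raise ValueError(f"tree leaves absent from pattern: {sorted(missing)}")
        self.tree = tree
        self.clogs = list(pattern.clogs)
        self.n_fam = pattern.n_clogs
        self.post_nodes = list(tree.postorder())
        self.leaf_onehot: dict[str, np.ndarray] = {}
        presence = pattern.presence
        for leaf in tree.leaf_ids:
            state = presence[pattern.strain_index(leaf)].astype(np.float64)
            self.leaf_onehot[leaf] = np.stack([1.0 - state, state], axis=1)

    def _up_pass(self, model: GainLossModel, rate: float, leaf_data=None):
        """Partial likelihoods per node; returns (up, upscale, msg, msgscale)."""
        up: dict[str, np.ndarray] = {}
        upscale: dict[str, np.ndarray] = {}
        msg: dict[str, np.ndarray] = {}
        msgscale: dict[str, np.ndarray] = {}
        leaf_data = leaf_data or self.leaf_onehot
        n = next(iter(leaf_data.values())).shape[0]
        for node in self.post_nodes:
            if node.is_leaf:
                up[node.id] = leaf_data[node.id]
                upscale[node.id] = np.zeros(n)
            else:
                partial = np.ones((n, 2))
                scale = np.zeros(n)
                for child in node.children:
                    partial = partial * msg[child.id]
                    scale = scale + msgscale[child.id]
                norm = partial.max(axis=1)
                norm = np.where(norm > 0, norm, 1.0)
                up[node.id] = partial / norm[:, None]
                upscale[node.id] = scale + np.log(norm)
            if node.parent is not None:
                p = branch_transition_probs(model, node.length, rate)
                msg[node.id] = up[node.id] @ p.T
                msgscale[node.id] = upscale[node.id]
        return up, upscale, msg, msgscale

    def _per_category_loglik(self, model: GainLossModel):
        """(K, F) per-category per-family log-likelihoods, plus log p(all-absent)."""
        pi = model.pi
        rates = model.category_rates
        out = np.empty((len(rates), self.n_fam))
        absent = {l: np.array([[1.0, 0.0]]) for l in self.tree.leaf_ids}
        log_p0 = np.empty(len(rates))
        for k, rate in enumerate(rates):
            up, upscale, _, _ = self._up_pass(model, rate)
            lik = up[self.tree.root.id] @ pi
            out[k] = np.log(lik) + upscale[self.tree.root.id]
            up0, upscale0, _, _ = self._up_pass(model, rate, leaf_data=absent)
            log_p0[k] = np.log(up0[self.tree.root.id] @ pi)[0] + upscale0[self.tree.root.id][0]
        return out, log_p0

    def loglik(self, model: GainLossModel, condition_observable: bool = True) -> float:
        per_cat, log_p0 = self._per_category_loglik(model)
        k = per_cat.shape[0]
        m = per_cat.max(axis=0)
        fam_log = m + np.log(np.exp(per_cat - m).sum(axis=0)) - np.log(k)
        total = fam_log.sum()
        if condition_observable:
            p0 = np.exp(log_p0).mean()
            if p0 >= 1.0 - 1e-15:
                return -np.inf  # degenerate: everything unobservable
            total -= self.n_fam * np.log1p(-p0)
        return float(total)

    def posteriors(self, model: GainLossModel) -> dict[str, np.ndarray]:
        """Marginal posterior P(present) per node over families, mixed over categories."""
        pi = model.pi
        rates = model.category_rates
        joint: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {
            n.id: [] for n in self.tree.preorder()
        }
        for rate in rates:
            up, upscale, msg, msgscale = self._up_pass(model, rate)
            down: dict[str, np.ndarray] = {self.tree.root.id: np.tile(pi, (self.n_fam, 1))}
            downscale: dict[str, np.ndarray] = {self.tree.root.id: np.zeros(self.n_fam)}
            for node in self.tree.preorder():
                for child in node.children:
                    sib = np.ones((self.n_fam, 2))
                    sibscale = np.zeros(self.n_fam)
                    for other in node.children:
                        if other is not child:
                            sib = sib * msg[other.id]
                            sibscale = sibscale + msgscale[other.id]
                    p = branch_transition_probs(model, child.length, rate)
                    d = (down[node.id] * sib) @ p
                    norm = d.max(axis=1)
                    norm = np.where(norm > 0, norm, 1.0)
                    down[child.id] = d / norm[:, None]
                    downscale[child.id] = downscale[node.id] + sibscale + np.log(norm)
            for node in self.tree.preorder():
                j = up[node.id] * down[node.id]
                joint[node.id].append((j, upscale[node.id] + downscale[node.id]))
        post: dict[str, np.ndarray] = {}
        for nid, parts in joint.items():
            scales = np.stack([s for _, s in parts])
            m = scales.max(axis=0)
            acc = np.zeros((self.n_fam, 2))
            for (j, s) in parts:
                acc += j * np.exp(s - m)[:, None]
            post[nid] = acc[:, 1] / acc.sum(axis=1)
        return post


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def fit_gainloss(
    pattern: PhyleticPattern,
    tree: EvoTree,
    k_gamma: int = 4,
    root_prior: str | float = "stationary",
) -> tuple[GainLossModel, float]:
    """Fit (alpha, beta[, gamma shape]) by maximum likelihood.

    The likelihood is conditioned on families being present in >= 1 tip.
    Returns the MLE model and the converged log-likelihood.
    """
    presence = pattern.presence
    if presence.all():
        raise ValueError("rates unidentifiable: every family present in every strain")
    if not presence.any():
        raise ValueError("rates unidentifiable: no family present anywhere")
    pruner = _Pruner(pattern, tree)
    height = max(tree.depths()[l] for l in tree.leaf_ids)
    p_bar = float(presence.mean())
    rate0 = 1.0 / height
    x0 = [np.log(rate0 * max(p_bar, 0.05)), np.log(rate0 * max(1.0 - p_bar, 0.05))]
    if k_gamma > 1:
        x0.append(0.0)  # log shape

    def nll(x):
        try:
            model = GainLossModel(
                alpha=float(np.exp(x[0])),
                beta=float(np.exp(x[1])),
                k_gamma=k_gamma,
                shape=float(np.exp(x[2])) if k_gamma > 1 else 1.0,
                root_prior=root_prior,
            )
            return -pruner.loglik(model)
        except (FloatingPointError, OverflowError):
            return 1e300

    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000})
    model = GainLossModel(
        alpha=float(np.exp(res.x[0])),
        beta=float(np.exp(res.x[1])),
        k_gamma=k_gamma,
        shape=float(np.exp(res.x[2])) if k_gamma > 1 else 1.0,
        root_prior=root_prior,
    )
    return model, float(-res.fun)


def total_loglik(
    model: GainLossModel,
    pattern: PhyleticPattern,
    tree: EvoTree,
    condition_observable: bool = True,
) -> float:
    """Pruning log-likelihood of the pattern at fixed parameters."""
    return _Pruner(pattern, tree).loglik(model, condition_observable=condition_observable)


# ---------------------------------------------------------------------------
# Ancestral states and events
# ---------------------------------------------------------------------------


@dataclass
class AncestralStates:
    clogs: list[str]
    node_ids: list[str]                       # internal node ids, preorder
    posterior: dict[str, np.ndarray]          # node id -> P(present) per family
    cutoff: float = 0.9

    def binarized(self, node_id: str) -> np.ndarray:
        """Per-family state at ``node_id``: 1, 0, or AMBIGUOUS (-1)."""
        p = self.posterior[node_id]
        out = np.full(p.shape, AMBIGUOUS, dtype=np.int8)
        out[p >= self.cutoff] = 1
        out[1.0 - p >= self.cutoff] = 0
        return out

    def root_family_count(self, root_id: str) -> int:
        return int((self.posterior[root_id] >= self.cutoff).sum())


def ancestral_posteriors(
    model: GainLossModel,
    pattern: PhyleticPattern,
    tree: EvoTree,
    cutoff: float = 0.9,
) -> AncestralStates:
    """Marginal posterior probability of presence for every internal node."""
    pruner = _Pruner(pattern, tree)
    post = pruner.posteriors(model)
    internal = [n.id for n in tree.preorder() if not n.is_leaf]
    return AncestralStates(
        clogs=list(pattern.clogs),
        node_ids=internal,
        posterior={nid: post[nid] for nid in internal},
        cutoff=cutoff,
    )


@dataclass
class BranchEvents:
    """Per-branch gain/loss totals and family lists, keyed by child node id."""

    gains: dict[str, list[str]] = field(default_factory=dict)
    losses: dict[str, list[str]] = field(default_factory=dict)

    def n_gained(self, branch: str) -> int:
        return len(self.gains[branch])

    def n_lost(self, branch: str) -> int:
        return len(self.losses[branch])


def count_events(
    states: AncestralStates,
    pattern: PhyleticPattern,
    tree: EvoTree,
) -> BranchEvents:
    """Per-branch gains (parent absent, child present) and losses (reverse).

    Tips use their observed states; branches touching an ambiguous ancestral
    state contribute no event for that family.
    """
    presence = pattern.presence
    clogs = np.array(states.clogs)
    node_state: dict[str, np.ndarray] = {}
    for node in tree.preorder():
        if node.is_leaf:
            node_state[node.id] = presence[pattern.strain_index(node.id)].astype(np.int8)
        else:
            node_state[node.id] = states.binarized(node.id)
    events = BranchEvents()
    for node in tree.preorder():
        if node.parent is None:
            continue
        parent = node_state[node.parent.id]
        child = node_state[node.id]
        ok = (parent != AMBIGUOUS) & (child != AMBIGUOUS)
        gained = ok & (parent == 0) & (child == 1)
        lost = ok & (parent == 1) & (child == 0)
        events.gains[node.id] = list(clogs[gained])
        events.losses[node.id] = list(clogs[lost])
    return events


def fixed_genes_per_node(pattern: PhyleticPattern, tree: EvoTree) -> dict[str, list[str]]:
    """Families present in every leaf below a node and in no other strain.

    Computed for internal nodes only (at the root the "no other strain"
    condition is vacuous, so families present everywhere are fixed there).
    """
    presence = pattern.presence
    leaf_row = {l: pattern.strain_index(l) for l in tree.leaf_ids}
    out: dict[str, list[str]] = {}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        below = tree.leafset_below(node)
        mask = np.zeros(pattern.n_strains, dtype=bool)
        for l in below:
            mask[leaf_row[l]] = True
        inside_all = presence[mask].all(axis=0)
        outside_any = presence[~mask].any(axis=0) if (~mask).any() else np.zeros(pattern.n_clogs, dtype=bool)
        fixed = inside_all & ~outside_any
        out[node.id] = [c for c, f in zip(pattern.clogs, fixed) if f]
    return out
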
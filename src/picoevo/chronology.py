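"""Time calibration and per-My evolutionary rates.

The recommended path is to supply a chronogram directly (branch durations in
My).  When only a substitutions/site tree is available, a simplified
relative-time scaler is provided: each internal node gets a relative depth
equal to the mean path length to its descendant leaves, monotonicity is
enforced by upward max-propagation, and a single least-squares scale factor
maps relative depths onto the calibration intervals.  This is a deliberate
simplification of full relative-rate dating frameworks; it yields an
ultrametric chronogram adequate for the per-branch rate regressions, which
only need branch durations.

Rates are estimated by through-origin least squares of per-branch event
counts on branch durations, separately for internal and terminal branches
(a zero-duration branch must carry zero expected events, hence no
intercept).  Fixed-gene / fixed-variant counts attach to the child node of
each internal branch; terminal branches are excluded from fixation rates
because a strain-specific item cannot be called fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .model import EvoTree, TreeNode


@dataclass
class Calibration:
    node_id: str
    min_age: float  # My
    max_age: float

    def __post_init__(self) -> None:
        if not (0 <= self.min_age < self.max_age):
            raise ValueError("calibration requires 0 <= min_age < max_age")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.min_age + self.max_age)


def calibrate_relative(tree: EvoTree, calibrations: list[Calibration]) -> EvoTree:
    """Scale a substitutions/site tree into an ultrametric chronogram (My).

    Steps: (1) relative node depth = mean node-to-descendant-leaf path
    length; (2) parent >= child enforced by upward max-propagation; (3) a
    single positive scale factor chosen by least squares against calibration
    midpoints, constrained into the intersection of the per-calibration
    feasible intervals (midpoint fallback when they conflict).
    """
    if not calibrations:
        raise ValueError("at least one calibration is required")
    for cal in calibrations:
        if cal.node_id not in tree:
            raise ValueError(f"calibration node {cal.node_id!r} not in tree")
        if tree.node(cal.node_id).is_leaf:
            raise ValueError(f"calibration node {cal.node_id!r} is a leaf")

    # (1) mean distance to descendant leaves
    rel: dict[str, float] = {}
    counts: dict[str, int] = {}
    for node in tree.postorder():
        if node.is_leaf:
            rel[node.id] = 0.0
            counts[node.id] = 1
        else:
            total = 0.0
            n = 0
            for child in node.children:
                total += counts[child.id] * (rel[child.id] + child.length)
                n += counts[child.id]
            rel[node.id] = total / n
            counts[node.id] = n
    # (2) monotonicity
    for node in tree.postorder():
        if node.children:
            rel[node.id] = max(rel[node.id], max(rel[c.id] for c in node.children))

    # (3) scale factor
    depths = np.array([rel[c.node_id] for c in calibrations])
    if np.any(depths <= 0):
        bad = [c.node_id for c, d in zip(calibrations, depths) if d <= 0]
        raise ValueError(f"no positive scale maps calibrated nodes {bad} (zero relative depth)")
    mids = np.array([c.midpoint for c in calibrations])
    s_ls = float(depths @ mids / (depths @ depths))
    lo = max(c.min_age / d for c, d in zip(calibrations, depths))
    hi = min(c.max_age / d for c, d in zip(calibrations, depths))
    if lo <= hi:
        scale = min(max(s_ls, lo), hi)
    else:
        scale = s_ls  # calibration intervals conflict: midpoint least squares
    if scale <= 0:
        raise ValueError("contradictory calibrations: no positive scale factor")

    ages = {nid: scale * r for nid, r in rel.items()}
    durations = {}
    for node in tree.preorder():
        if node.parent is not None:
            durations[node.id] = max(ages[node.parent.id] - ages[node.id], 0.0)
    return tree.with_lengths(durations, "My")


def substitutions_per_branch(tree: EvoTree, total_residues: int) -> dict[str, float]:
    """Per-branch substitution counts = branch length x alignment residues."""
    if tree.unit != "subs/site":
        raise ValueError("substitution counts need a substitutions/site tree")
    if total_residues <= 0:
        raise ValueError("total_residues must be > 0")
    return {
        n.id: n.length * total_residues
        for n in tree.preorder()
        if n.parent is not None
    }


@dataclass
class RateFit:
    slope: float          # events per My
    se: float
    adj_r2: float
    p_value: float
    n: int
    branch_class: str


def _branches(tree: EvoTree, branch_class: str) -> list[TreeNode]:
    if branch_class not in ("internal", "terminal", "all"):
        raise ValueError(f"unknown branch class {branch_class!r}")
    out = []
    for node in tree.preorder():
        if node.parent is None:
            continue
        if branch_class == "all":
            out.append(node)
        elif branch_class == "terminal" and node.is_leaf:
            out.append(node)
        elif branch_class == "internal" and not node.is_leaf:
            out.append(node)
    return out


def rate_regression(
    counts: dict[str, float],
    tree_my: EvoTree,
    branch_class: str = "all",
) -> RateFit:
    """Through-origin OLS of per-branch counts on branch durations (My).

    ``counts`` maps child-node ids to event counts; branches of the stated
    class missing from ``counts`` enter with count 0.  R-squared is computed
    about zero, as appropriate for a no-intercept model.
    """
    if tree_my.unit != "My":
        raise ValueError("rate regression needs a chronogram in My")
    branches = _branches(tree_my, branch_class)
    if len(branches) < 3:
        raise ValueError(
            f"insufficient branches in class {branch_class!r} ({len(branches)} < 3)"
        )
    x = np.array([b.length for b in branches], dtype=float)
    y = np.array([counts.get(b.id, 0.0) for b in branches], dtype=float)
    if not y.any():
        return RateFit(0.0, 0.0, float("nan"), 1.0, len(branches), branch_class)
    res = sm.OLS(y, x[:, None]).fit()
    return RateFit(
        slope=float(res.params[0]),
        se=float(res.bse[0]),
        adj_r2=float(res.rsquared_adj),
        p_value=float(res.pvalues[0]),
        n=len(branches),
        branch_class=branch_class,
    )


def fixation_rate_regression(
    fixed_counts: dict[str, int],
    tree_my: EvoTree,
) -> RateFit:
    """Fixation rate per My over internal branches only.

    ``fixed_counts`` maps internal node ids to the number of genes or
    variants fixed at that node; each internal branch is paired with the
    count at its child node.  Terminal branches are excluded by definition.
    """
    for nid in fixed_counts:
        if nid in tree_my and tree_my.node(nid).is_leaf:
            raise ValueError(
                f"fixed counts on terminal branch {nid!r}: fixation is defined "
                "for internal branches only"
            )
    counts = {k: float(v) for k, v in fixed_counts.items()}
    return rate_regression(counts, tree_my, branch_class="internal")
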
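"""Core/accessory/unique classification, rarefaction, and core-size asymptote.

A CLOG is *core* in a taxonomic group when it is present in at least 90% of
the group's strains (strict 100% mode also available), *unique* when present
in exactly one strain overall, and *accessory* otherwise.  Rarefaction
follows the fully random genome-integration-order scheme: pan and core sizes
are tracked along random permutations of the genomes and summarized by
median and quartiles at each depth.  The asymptotic core size is estimated
by fitting the exponential-decay law

    core(n) = kappa * exp(-n / tau) + omega

to the median core curve, omega being the projected persistent core.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .model import PhyleticPattern, StrainMetadata

LEVELS = ("all", "sub_cluster", "clade")


@dataclass
class PangenomeSummary:
    level: str
    core_fraction: float
    groups: dict[str, list[str]]                  # group label -> strains
    clog_class: dict[str, str]                    # CLOG -> core | accessory | unique
    core_by_group: dict[str, set[str]]            # group label -> core CLOGs
    per_strain: dict[str, dict[str, int]]         # strain -> class -> count
    pan_size: int = 0
    skipped_groups: list[str] = field(default_factory=list)

    def core_size(self, group: str) -> int:
        return len(self.core_by_group[group])


def classify_clogs(
    pattern: PhyleticPattern,
    metadata: StrainMetadata | None = None,
    level: str = "all",
    core_fraction: float = 0.9,
    min_group_size: int = 3,
) -> PangenomeSummary:
    """Classify every CLOG as core (at ``level``), accessory or unique.

    ``level`` is ``all`` (one group of all strains) or a metadata column
    (``sub_cluster``, ``clade``); groups with fewer than ``min_group_size``
    genomes are skipped.  A CLOG is core in group G when present in at least
    ``ceil(core_fraction * |G|)`` of its strains; ``core_fraction=1.0`` gives
    the strict all-strains reading.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}; use one of {LEVELS}")
    presence = pattern.presence
    if level == "all":
        groups = {"all": list(pattern.strains)}
    else:
        if metadata is None:
            raise ValueError(f"metadata required for level {level!r}")
        metadata.check_covers(pattern)
        groups = metadata.groups(level)
        groups = {g: [s for s in members if s in pattern._strain_index]
                  for g, members in groups.items()}
    skipped = sorted(g for g, members in groups.items() if len(members) < min_group_size)
    groups = {g: members for g, members in groups.items() if len(members) >= min_group_size}

    overall = presence.sum(axis=0)  # strains per CLOG
    core_by_group: dict[str, set[str]] = {}
    core_any = np.zeros(pattern.n_clogs, dtype=bool)
    for g, members in groups.items():
        idx = [pattern.strain_index(s) for s in members]
        need = math.ceil(core_fraction * len(members))
        mask = presence[idx].sum(axis=0) >= need
        core_by_group[g] = {c for c, m in zip(pattern.clogs, mask) if m}
        core_any |= mask

    clog_class: dict[str, str] = {}
    for j, clog in enumerate(pattern.clogs):
        if overall[j] == 0:
            continue  # unobserved family: not part of the pan-genome
        if core_any[j]:
            clog_class[clog] = "core"
        elif overall[j] == 1:
            clog_class[clog] = "unique"
        else:
            clog_class[clog] = "accessory"

    per_strain: dict[str, dict[str, int]] = {}
    for i, strain in enumerate(pattern.strains):
        counts = {"core": 0, "accessory": 0, "unique": 0}
        for j, clog in enumerate(pattern.clogs):
            if presence[i, j]:
                counts[clog_class[clog]] += 1
        per_strain[strain] = counts

    return PangenomeSummary(
        level=level,
        core_fraction=core_fraction,
        groups=groups,
        clog_class=clog_class,
        core_by_group=core_by_group,
        per_strain=per_strain,
        pan_size=int((overall > 0).sum()),
        skipped_groups=skipped,
    )


@dataclass
class RarefactionCurve:
    n: np.ndarray            # genome depths 1..N
    pan_median: np.ndarray
    pan_q1: np.ndarray
    pan_q3: np.ndarray
    core_median: np.ndarray
    core_q1: np.ndarray
    core_q3: np.ndarray
    n_permutations: int
    core_fraction: float
    seed: int


def _prefix_sizes(presence: np.ndarray, order: np.ndarray, core_fraction: float):
    """Pan and core sizes along one genome-integration order."""
    cum = np.cumsum(presence[order], axis=0)
    n = np.arange(1, presence.shape[0] + 1)
    need = np.ceil(core_fraction * n).astype(int)
    pan = (cum > 0).sum(axis=1)
    core = (cum >= need[:, None]).sum(axis=1)
    return pan, core


def rarefaction(
    pattern: PhyleticPattern,
    n_permutations: int = 1000,
    core_fraction: float = 0.9,
    seed: int = 0,
    exhaustive: bool = False,
) -> RarefactionCurve:
    """Pan/core rarefaction over random genome-integration orders.

    For each permutation and each prefix of n genomes, pan = families
    present in >= 1 of the n, core = families present in at least
    ``core_fraction`` of the n.  Quartiles are computed across permutations
    at fixed n.  With ``exhaustive=True`` every genome order is used exactly
    once (only sensible for small genome sets; N! orders).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    presence = pattern.presence.astype(np.int32)
    n_strains = pattern.n_strains
    if exhaustive:
        import itertools as _it
        import math as _math

        if _math.factorial(n_strains) > 50_000:
            raise ValueError("exhaustive enumeration infeasible for this many genomes")
        orders = [np.array(o) for o in _it.permutations(range(n_strains))]
    else:
        orders = [rng.permutation(n_strains) for _ in range(n_permutations)]
    pans = np.empty((len(orders), n_strains), dtype=np.int64)
    cores = np.empty((len(orders), n_strains), dtype=np.int64)
    for p, order in enumerate(orders):
        pans[p], cores[p] = _prefix_sizes(presence, order, core_fraction)
    q1, med, q3 = np.percentile(pans, [25, 50, 75], axis=0)
    cq1, cmed, cq3 = np.percentile(cores, [25, 50, 75], axis=0)
    return RarefactionCurve(
        n=np.arange(1, n_strains + 1),
        pan_median=med, pan_q1=q1, pan_q3=q3,
        core_median=cmed, core_q1=cq1, core_q3=cq3,
        n_permutations=len(orders),
        core_fraction=core_fraction,
        seed=seed,
    )


@dataclass
class AsymptoteFit:
    kappa: float
    tau: float
    omega: float
    omega_se: float
    residuals: np.ndarray
    rss: float


def fit_core_asymptote(curve: RarefactionCurve) -> AsymptoteFit:
    """Fit core(n) = kappa*exp(-n/tau) + omega to the median core curve.

    ``omega`` is the asymptotic (persistent) core size.  Starting values:
    kappa = first - last, tau = N/3, omega = last.
    """
    n = curve.n.astype(float)
    y = np.asarray(curve.core_median, dtype=float)
    if np.ptp(y) < 1e-12:
        return AsymptoteFit(0.0, float(len(n)) / 3.0, float(y[0]), 0.0,
                            np.zeros_like(y), 0.0)

    def model(x, kappa, tau, omega):
        return kappa * np.exp(-x / tau) + omega

    p0 = (float(y[0] - y[-1]), float(len(n)) / 3.0, float(y[-1]))
    try:
        popt, pcov = curve_fit(model, n, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"core-asymptote fit did not converge (starting values {p0})"
        ) from exc
    resid = y - model(n, *popt)
    omega_se = float(np.sqrt(pcov[2, 2])) if np.all(np.isfinite(pcov)) else float("nan")
    return AsymptoteFit(
        kappa=float(popt[0]), tau=float(popt[1]), omega=float(popt[2]),
        omega_se=omega_se, residuals=resid, rss=float((resid**2).sum()),
    )
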
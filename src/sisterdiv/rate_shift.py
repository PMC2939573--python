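"""Maximum-likelihood birth-death rate fitting on richness trees.

The likelihood is the *taxonomic* (stem-age) likelihood: the probability of
each terminal clade's extant richness n_i given its stem age t_i under a
constant-rate birth-death process with net diversification r = lambda - mu
and relative extinction eps = mu/lambda, conditioned on the clade surviving
to the present.  Conditioned on survival the clade size is geometric,

    P(N = n | N >= 1) = (1 - beta) * beta^(n-1),
    beta = (e^{rt} - 1) / (e^{rt} - eps),

which reduces to beta = 1 - e^{-rt} for pure birth (eps = 0).  The total
log-likelihood is the sum over terminal clades; internal branching times
carry no information in this likelihood, so fits depend on the tree only
through the partition of tips into rate classes and their stem ages.

Three fitting modes:

* :func:`fit_fixed_rate` — one (r, eps) for the whole tree (eps fixed or free);
* :func:`fit_flexible_rate` — an ancestral rate shifting to a descendant rate
  along the single best branch, scored against the fixed model by LRT;
* :func:`stepwise_shift_search` — stepwise addition of shifts, each class with
  its own free (r, eps), accepted while AIC improves by at least a cutoff
  (default 4); the shifted class applies from the selected stem branch down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import optimize, stats

from sisterdiv.core_io import RichnessTree

__all__ = [
    "BDParams", "RateShiftFit", "clade_richness_logprob",
    "fit_fixed_rate", "fit_flexible_rate", "stepwise_shift_search",
]

_EPS_MAX = 0.999
_R_FLOOR = 1e-10


@dataclass(frozen=True)
class BDParams:
    """Net diversification rate r >= 0 and relative extinction eps in [0, 1)."""

    r: float
    eps: float = 0.0

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError(f"net diversification rate must be >= 0 (got {self.r})")
        if not 0.0 <= self.eps < 1.0:
            raise ValueError(f"relative extinction must lie in [0, 1) (got {self.eps})")

    @property
    def speciation(self) -> float:
        """lambda = r / (1 - eps)"""
        return self.r / (1.0 - self.eps)

    @property
    def extinction(self) -> float:
        """mu = lambda * eps"""
        return self.speciation * self.eps


@dataclass(frozen=True)
class RateShiftFit:
    """A fitted diversification model on a richness tree."""

    model: str                                  #: fixed | flexible | stepwise
    classes: tuple[BDParams, ...]               #: base class first
    shift_branches: tuple[tuple[str, ...], ...] #: each = sorted tip labels below the shift stem
    logL: float
    n_params: int
    lrt_p: float | None = None
    class_of_tip: dict = field(default=None, repr=False, compare=False)

    @property
    def AIC(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.logL

    @property
    def n_shifts(self) -> int:
        return len(self.shift_branches)


def clade_richness_logprob(n: int, t: float, params: BDParams) -> float:
    """Log P(clade of n extant species | stem age t, survival).

    Geometric in n with parameter beta = (e^{rt}-1)/(e^{rt}-eps); at r = 0
    the process cannot diversify (lambda = r/(1-eps) = 0), so all mass sits
    on n = 1.
    """
    if n < 1 or int(n) != n:
        raise ValueError(f"richness must be a positive integer (got {n})")
    if t <= 0:
        raise ValueError(f"stem age must be > 0 (got {t})")
    return float(_loglik_vec(np.array([n]), np.array([t]), params.r, params.eps))


def _logprob_terms(n: np.ndarray, t: np.ndarray, r: float, eps: float) -> np.ndarray:
    """Vectorized log[(1-beta) beta^(n-1)] with overflow-safe tails."""
    rt = r * t
    n = np.asarray(n, dtype=float)
    out = np.empty_like(rt, dtype=float)
    big = rt > 500.0  # e^rt overflows; beta -> 1
    small = ~big
    if np.any(small):
        em = np.expm1(rt[small])
        denom = em + (1.0 - eps)
        with np.errstate(divide="ignore"):
            log_beta = np.where(em > 0, np.log(em) - np.log(denom), -np.inf)
        log_1mbeta = math.log1p(-eps) - np.log(denom)
        ns = n[small]
        term = np.where(ns == 1, log_1mbeta, log_1mbeta + (ns - 1) * log_beta)
        out[small] = term
    if np.any(big):
        # log beta ~ -(1-eps) e^{-rt};  log(1-beta) ~ log(1-eps) - rt
        rb = rt[big]
        log_beta = -(1.0 - eps) * np.exp(-rb)
        log_1mbeta = math.log1p(-eps) - rb
        nb = n[big]
        out[big] = log_1mbeta + (nb - 1) * log_beta
    return out


def _loglik_vec(n: np.ndarray, t: np.ndarray, r: float, eps: float) -> float:
    if r <= 0:
        # degenerate: no diversification; P(1) = 1, P(n>1) = 0
        return 0.0 if np.all(n == 1) else -np.inf
    return float(_logprob_terms(n, t, r, eps).sum())


# ---------------------------------------------------------------------------
# optimization


def _r_upper(n: np.ndarray, t: np.ndarray) -> float:
    """Generous upper bound for r: log total richness over min stem age."""
    return max(1.0, 5.0 * math.log(float(n.sum()) + 2.0) / float(t.min()))


def _grid_loglik(
    n: np.ndarray, t: np.ndarray, r_grid: np.ndarray, eps_grid: np.ndarray
) -> np.ndarray:
    """logL on an (r, eps) grid, vectorized over clades; shape (R, E)."""
    rt = r_grid[:, None, None] * t[None, None, :]          # (R, 1, m)
    em = np.expm1(np.minimum(rt, 500.0))
    denom = em + (1.0 - eps_grid[None, :, None])           # (R, E, m)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_beta = np.log(em) - np.log(denom)
        log_1mbeta = np.log1p(-eps_grid)[None, :, None] - np.log(denom)
        terms = log_1mbeta + (n[None, None, :] - 1.0) * np.where(
            n[None, None, :] > 1, log_beta, 0.0)
    return np.nansum(terms, axis=2)


def _fit_class(
    n: np.ndarray, t: np.ndarray, eps: float | Literal["free"]
) -> tuple[BDParams, float]:
    """Maximize the richness log-likelihood for one rate class.

    Coarse vectorized grid search (log-spaced in r) followed by a single
    bounded polish; deterministic, no stochastic restarts.
    """
    n = np.asarray(n, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.all(n == 1):
        # boundary MLE: no diversification signal
        e = 0.0 if eps == "free" else float(eps)
        return BDParams(0.0, e), 0.0
    r_hi = _r_upper(n, t)
    r_grid = np.geomspace(1e-6 * r_hi, r_hi, 64)
    if eps != "free":
        e = float(eps)
        ll = _grid_loglik(n, t, r_grid, np.array([e]))[:, 0]
        i = int(np.argmax(ll))
        lo = r_grid[max(i - 1, 0)]
        hi = r_grid[min(i + 1, r_grid.size - 1)]
        res = optimize.minimize_scalar(
            lambda r: -_loglik_vec(n, t, r, e),
            bounds=(lo, hi), method="bounded", options={"xatol": 1e-9})
        return BDParams(float(res.x), e), -float(res.fun)
    eps_grid = np.concatenate([np.linspace(0.0, 0.9, 10),
                               np.array([0.95, 0.98, _EPS_MAX])])
    ll = _grid_loglik(n, t, r_grid, eps_grid)
    i, j = np.unravel_index(int(np.argmax(ll)), ll.shape)
    res = optimize.minimize(
        lambda x: -_loglik_vec(n, t, x[0], x[1]),
        x0=np.array([r_grid[i], eps_grid[j]]),
        bounds=[(_R_FLOOR, r_hi), (0.0, _EPS_MAX)],
        method="L-BFGS-B")
    if not np.isfinite(res.fun):
        raise RuntimeError("rate/extinction optimization failed")
    return BDParams(float(res.x[0]), float(res.x[1])), -float(res.fun)


def _clade_arrays(rt: RichnessTree) -> tuple[list[str], np.ndarray, np.ndarray]:
    labels, ns, ts = [], [], []
    for label, n, t in rt.clades():
        labels.append(label)
        ns.append(n)
        ts.append(t)
    return labels, np.asarray(ns, dtype=float), np.asarray(ts, dtype=float)


def fit_fixed_rate(
    rt: RichnessTree, eps: float | Literal["free"] = 0.0
) -> RateShiftFit:
    """Fit a single diversification rate to all terminal clades.

    ``eps`` is either a fixed relative-extinction value or ``"free"`` to
    estimate it; n_params is 1 or 2 accordingly.
    """
    labels, n, t = _clade_arrays(rt)
    if len(labels) < 2:
        raise ValueError("need at least 2 terminal clades")
    params, logL = _fit_class(n, t, eps)
    return RateShiftFit(
        model="fixed",
        classes=(params,),
        shift_branches=(),
        logL=logL,
        n_params=1 if eps != "free" else 2,
        class_of_tip={l: 0 for l in labels},
    )


def _candidate_edges(
    rt: RichnessTree, internal_only: bool = False
) -> list[tuple[tuple[str, ...], frozenset]]:
    """Candidate shift edges as the sorted tip set below each, root excluded.

    An edge defines a candidate shift: the rate class applying from that stem
    branch down.  Proper-subset tip sets only, so the base class never
    empties.  With ``internal_only`` terminal edges are skipped — the
    ancestral/descendant two-rate model splits the tree at internal nodes,
    whereas the stepwise search may hang a shift on any branch.
    """
    all_tips = frozenset(rt.tip_labels)
    out = []
    for node in rt.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if internal_only and node.is_leaf():
            continue
        tips = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if tips == all_tips:
            continue
        out.append((tuple(sorted(tips)), tips))
    return out


def fit_flexible_rate(
    rt: RichnessTree, eps: float | Literal["free"] = 0.0
) -> RateShiftFit:
    """Fit an ancestral-to-descendant rate shift along the best single branch.

    For every internal branch, clades inside the subtree below it get rate r2
    and all others keep r1; both are fitted jointly (the likelihood
    separates).  The returned fit carries the best shift branch and an LRT p
    against the fixed single-rate model: chi-square with df = 1 when eps is
    fixed (one extra rate), df = 2 when eps is free per class.  Candidate
    shifts sit on branches subtending internal nodes, matching two-rate
    tree-splitting at nodes; the stepwise search also considers terminal
    branches.
    """
    labels, n, t = _clade_arrays(rt)
    if len(labels) < 3:
        raise ValueError("need at least 3 terminal clades")
    fixed = fit_fixed_rate(rt, eps)
    label_ix = {l: i for i, l in enumerate(labels)}
    best = None
    for tip_tuple, tips in _candidate_edges(rt, internal_only=True):
        inside = np.zeros(len(labels), dtype=bool)
        for l in tip_tuple:
            if l in label_ix:
                inside[label_ix[l]] = True
        if not inside.any() or inside.all():
            continue
        p_out, ll_out = _fit_class(n[~inside], t[~inside], eps)
        p_in, ll_in = _fit_class(n[inside], t[inside], eps)
        logL = ll_out + ll_in
        # likelihood ties happen when two placements induce the same partition
        # (a root child vs its sibling); report the shift on the smaller,
        # derived clade
        if (best is None or logL > best[0] + 1e-9
                or (abs(logL - best[0]) <= 1e-9 and len(tip_tuple) < len(best[1]))):
            best = (logL, tip_tuple, p_out, p_in, inside)
    if best is None:
        raise ValueError("no internal branch available for a rate shift")
    logL, tip_tuple, p_out, p_in, inside = best
    df = 1 if eps != "free" else 2
    lrt = 2.0 * (logL - fixed.logL)
    lrt_p = float(stats.chi2.sf(max(lrt, 0.0), df))
    n_params = 2 if eps != "free" else 4
    class_of_tip = {l: (1 if inside[label_ix[l]] else 0) for l in labels}
    return RateShiftFit(
        model="flexible",
        classes=(p_out, p_in),
        shift_branches=(tip_tuple,),
        logL=logL,
        n_params=n_params,
        lrt_p=lrt_p,
        class_of_tip=class_of_tip,
    )


def _assign_classes(
    labels: Sequence[str],
    rt: RichnessTree,
    shift_sets: Sequence[frozenset],
) -> np.ndarray:
    """Class index per tip: most tip-ward (smallest) containing shift, else 0."""
    cls = np.zeros(len(labels), dtype=int)
    for i, l in enumerate(labels):
        best_j, best_size = 0, None
        for j, s in enumerate(shift_sets, start=1):
            if l in s and (best_size is None or len(s) < best_size):
                best_j, best_size = j, len(s)
        cls[i] = best_j
    return cls


def stepwise_shift_search(
    rt: RichnessTree, delta_aic_cut: float = 4.0
) -> RateShiftFit:
    """Stepwise-AIC search for multiple diversification-rate shifts.

    Starts from the single-class model with free extinction; at each step the
    shift (at some subtree's stem branch) that most decreases AIC is added,
    stopping when the best improvement is below ``delta_aic_cut``.  Every
    class has its own (r, eps); each accepted shift adds one location
    parameter, so n_params = 2 * classes + shifts.
    """
    if delta_aic_cut <= 0:
        raise ValueError("delta_aic_cut must be > 0")
    labels, n, t = _clade_arrays(rt)
    label_ix = {l: i for i, l in enumerate(labels)}
    candidates = _candidate_edges(rt)

    cache: dict[bytes, tuple[BDParams, float]] = {}

    def fit_mask(mask: np.ndarray) -> tuple[BDParams, float]:
        key = mask.tobytes()
        if key not in cache:
            cache[key] = _fit_class(n[mask], t[mask], "free")
        return cache[key]

    def fit_assignment(shift_sets: list[frozenset]) -> tuple[float, tuple[BDParams, ...]]:
        cls = _assign_classes(labels, rt, shift_sets)
        params, logL = [], 0.0
        for c in range(len(shift_sets) + 1):
            mask = cls == c
            if not mask.any():
                return -np.inf, ()
            p, ll = fit_mask(mask)
            params.append(p)
            logL += ll
        return logL, tuple(params)

    shifts: list[tuple[tuple[str, ...], frozenset]] = []
    logL, params = fit_assignment([])
    n_params = 2
    aic = 2 * n_params - 2 * logL
    while True:
        chosen = None
        for tip_tuple, tips in candidates:
            if any(tips == s for _, s in shifts):
                continue
            cand_logL, cand_params = fit_assignment(
                [s for _, s in shifts] + [tips])
            if not cand_params:
                continue
            k = 2 * (len(shifts) + 2) + (len(shifts) + 1)
            cand_aic = 2 * k - 2 * cand_logL
            # AIC ties (equivalent partitions, e.g. a root child vs its
            # sibling) resolve to the smaller, derived clade
            if (chosen is None or cand_aic < chosen[0] - 1e-9
                    or (abs(cand_aic - chosen[0]) <= 1e-9
                        and len(tip_tuple) < len(chosen[3][0]))):
                chosen = (cand_aic, cand_logL, cand_params, (tip_tuple, tips), k)
        if chosen is None or aic - chosen[0] < delta_aic_cut:
            break
        aic, logL, params = chosen[0], chosen[1], chosen[2]
        shifts.append(chosen[3])
        n_params = chosen[4]
    cls = _assign_classes(labels, rt, [s for _, s in shifts])
    return RateShiftFit(
        model="stepwise",
        classes=params,
        shift_branches=tuple(tt for tt, _ in shifts),
        logL=logL,
        n_params=n_params,
        class_of_tip={l: int(cls[label_ix[l]]) for l in labels},
    )
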
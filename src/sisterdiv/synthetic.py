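"""Generators for the statistical structures the analysis assumes.

Four layers, each seeded and reproducible (one ``numpy.random.Generator``
stream per call):

* uniform ERM diversity splits of ``n`` species between two sisters;
* sister-pair tables with clade richness drawn from survival-conditioned
  birth-death clades at a shared stem age, with an optional rate bias between
  galler and non-galler (rate_ratio = 1 is the ERM-like null);
* event-driven (Gillespie) birth-death trees, complete with extinct lineages,
  pruned to the reconstructed extant-only ultrametric tree, with an optional
  rate shift applying to one subtree;
* collapse of a reconstructed tree at a chosen age into a richness tree — the
  tips-as-clades structure the taxonomic likelihood consumes.

Defaults emulate clade-level insect diversification: net rates of a few
percent per Ma (the scale estimated for Acacia thrips and nematine sawflies)
and host-MRCA ages spanning 0-150 Ma, with a point mass of exact ties at 0
reproducing comparisons in which neither clade's host MRCA is resolvable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import dendropy
import numpy as np

from sisterdiv.core_io import RichnessTree, SisterPair, SisterPairTable, \
    richness_tree_from_newick

__all__ = [
    "BDSimConfig", "simulate_erm_splits", "simulate_clade_richness",
    "generate_sister_table", "simulate_bd_tree", "collapse_to_richness_tree",
    "generate_richness_tree",
]

_SURVIVAL_CAP = 100_000


def simulate_erm_splits(n: int, reps: int, seed: int) -> np.ndarray:
    """Diversity splits (k, n-k) drawn uniformly from the ERM null.

    Returns an array of shape (reps, 2); k is uniform on {1..n-1}.
    """
    if n < 2 or reps < 1:
        raise ValueError("need n >= 2 and reps >= 1")
    rng = np.random.default_rng(seed)
    k = rng.integers(1, n, size=reps)
    return np.column_stack([k, n - k])


def simulate_clade_richness(
    r: float,
    eps: float,
    t: float,
    rng: np.random.Generator,
    condition_on_survival: bool = True,
) -> int:
    """Extant descendants of one stem lineage after time t (Gillespie).

    Count-only birth-death simulation with speciation lambda = r/(1-eps) and
    extinction mu = lambda*eps.  With ``condition_on_survival`` the outcome is
    rejection-sampled to be >= 1; otherwise 0 (extinction) is possible.
    """
    if t <= 0:
        raise ValueError("stem age must be > 0")
    lam = r / (1.0 - eps)
    mu = lam * eps
    total = lam + mu
    for _ in range(_SURVIVAL_CAP):
        alive = 1
        clock = 0.0
        while alive > 0:
            clock += rng.exponential(1.0 / (total * alive)) if total > 0 else math.inf
            if clock >= t:
                break
            if rng.random() < lam / total:
                alive += 1
            else:
                alive -= 1
        if alive > 0 or not condition_on_survival:
            return alive
    raise RuntimeError(
        "survival conditioning failed in 1e5 attempts; raise r or lower t")


def generate_sister_table(
    n_pairs: int,
    rate_ratio: float = 1.0,
    time_span: tuple[float, float] = (10.0, 60.0),
    seed: int = 0,
    r_base: float = 0.05,
    eps: float = 0.0,
    host_age_range: tuple[float, float] = (20.0, 150.0),
    host_tie_prob: float = 0.4,
) -> SisterPairTable:
    """Synthetic sister-pair table under an ERM-like null or a rate bias.

    Each pair shares a stem age drawn uniformly from ``time_span`` (Ma); the
    galler clade diversifies at net rate ``r_base * rate_ratio`` and the
    non-galler at ``r_base``, both survival-conditioned, so ``rate_ratio=1``
    gives exchangeable sisters.  With probability ``host_tie_prob`` a pair's
    host ages are both 0 (host MRCA unresolvable on either side), else each
    is uniform on ``host_age_range``.
    """
    if n_pairs < 1 or rate_ratio <= 0:
        raise ValueError("need n_pairs >= 1 and rate_ratio > 0")
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n_pairs):
        t = rng.uniform(*time_span)
        n_g = simulate_clade_richness(r_base * rate_ratio, eps, t, rng)
        n_n = simulate_clade_richness(r_base, eps, t, rng)
        if rng.random() < host_tie_prob:
            age_g = age_n = 0.0
        else:
            age_g = float(rng.uniform(*host_age_range))
            age_n = float(rng.uniform(*host_age_range))
        pairs.append(SisterPair(
            pair_id=f"pair{i + 1}",
            galler_name=f"galler{i + 1}", n_galler=int(n_g),
            host_age_galler=age_g,
            nongaller_name=f"nongaller{i + 1}", n_nongaller=int(n_n),
            host_age_nongaller=age_n,
        ))
    return SisterPairTable(tuple(pairs))


# ---------------------------------------------------------------------------
# birth-death tree simulation


@dataclass(frozen=True)
class BDSimConfig:
    """Configuration of one birth-death tree simulation.

    Exactly one stopping rule is used: ``root_age`` (run the two root
    lineages forward for a fixed time) or ``n_tips_target`` (stop when the
    extant lineage count first reaches the target; elapsed time becomes the
    root age).  ``shift_age`` (with ``lambda2``/``mu2``) switches one
    uniformly chosen lineage alive at that age — and all its descendants — to
    the post-shift rates.
    """

    lambda1: float
    mu1: float = 0.0
    lambda2: float | None = None
    mu2: float | None = None
    shift_age: float | None = None
    root_age: float | None = None
    n_tips_target: int | None = None
    seed: int = 0
    condition_on_survival: bool = True

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.mu1 < 0:
            raise ValueError("rates must be >= 0")
        if (self.root_age is None) == (self.n_tips_target is None):
            raise ValueError("exactly one of root_age / n_tips_target required")
        if self.shift_age is not None and (self.lambda2 is None or self.mu2 is None):
            raise ValueError("shift_age requires lambda2 and mu2")


class _Lineage:
    __slots__ = ("node", "cls")

    def __init__(self, node: dendropy.Node, cls: int):
        self.node = node
        self.cls = cls


def _simulate_once(cfg: BDSimConfig, rng: np.random.Generator) -> dendropy.Tree | None:
    """One forward Gillespie run; returns the complete tree or None (all dead).

    Time runs forward from 0; at the end it is flipped so node ages are
    backward from the present.
    """
    rates = {0: (cfg.lambda1, cfg.mu1)}
    if cfg.lambda2 is not None:
        rates[1] = (cfg.lambda2, cfg.mu2)
    use_age = cfg.root_age is not None
    horizon = cfg.root_age if use_age else math.inf
    shift_fwd = None
    if cfg.shift_age is not None:
        if not use_age:
            raise ValueError("shift_age requires the root_age stopping rule")
        shift_fwd = cfg.root_age - cfg.shift_age

    tree = dendropy.Tree()
    root = tree.seed_node
    root.birth_fwd = 0.0
    alive: list[_Lineage] = []
    for _ in range(2):
        child = dendropy.Node()
        child.birth_fwd = 0.0
        root.add_child(child)
        alive.append(_Lineage(child, 0))
    now = 0.0
    shifted = shift_fwd is None
    while alive:
        total = sum(sum(rates[l.cls]) for l in alive)
        wait = rng.exponential(1.0 / total) if total > 0 else math.inf
        nxt = now + wait
        if not shifted and nxt > shift_fwd:
            now = shift_fwd
            pick = alive[rng.integers(len(alive))]
            pick.cls = 1
            shifted = True
            continue
        if use_age and nxt >= horizon:
            break
        if not use_age and len(alive) >= cfg.n_tips_target:
            # target reached: the present sits at the would-be next event, so
            # terminal branches keep positive length (simple stop-at-n rule)
            if not math.isfinite(nxt):
                return None
            horizon = nxt
            break
        if not math.isfinite(nxt):
            break
        now = nxt
        # choose the lineage proportionally to its total rate
        weights = np.array([sum(rates[l.cls]) for l in alive])
        ix = rng.choice(len(alive), p=weights / weights.sum())
        lin = alive[ix]
        lam, mu = rates[lin.cls]
        if rng.random() < lam / (lam + mu):
            for _ in range(2):
                child = dendropy.Node()
                child.birth_fwd = now
                lin.node.add_child(child)
                alive.append(_Lineage(child, lin.cls))
            lin.node.death_fwd = now
            alive.remove(lin)
        else:
            lin.node.death_fwd = now
            lin.node.extinct = True
            alive.remove(lin)
    if not alive:
        return None
    if not use_age and (len(alive) < cfg.n_tips_target or not math.isfinite(horizon)):
        return None
    # close surviving lineages at the present and set edge lengths
    taxon_namespace = tree.taxon_namespace
    i_extant = i_extinct = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            end = getattr(node, "death_fwd", horizon)
            node.edge.length = end - node.birth_fwd
        if node.is_leaf():
            if getattr(node, "extinct", False):
                i_extinct += 1
                label = f"X{i_extinct}"
            else:
                i_extant += 1
                label = f"T{i_extant}"
            node.taxon = taxon_namespace.new_taxon(label)
    return tree


def _reconstructed(tree: dendropy.Tree) -> dendropy.Tree | None:
    """Extant-only tree: extinct subtrees removed, unifurcations suppressed."""
    extant = [t.label for t in tree.taxon_namespace if t.label.startswith("T")]
    if len(extant) < 2:
        return None
    rec = tree.extract_tree_with_taxa_labels(extant)
    # detach from the complete tree's namespace so pruning leaves it intact
    rec.migrate_taxon_namespace(dendropy.TaxonNamespace())
    return rec


def simulate_bd_tree(cfg: BDSimConfig) -> tuple[dendropy.Tree, dendropy.Tree]:
    """Simulate a birth-death tree; returns (complete, reconstructed).

    The complete tree keeps extinct lineages (tips ``X*``); the reconstructed
    tree contains extant tips (``T*``) only and is ultrametric.  With
    ``condition_on_survival`` the run is rejection-sampled until at least two
    extant tips survive (capped at 1e5 attempts).
    """
    rng = np.random.default_rng(cfg.seed)
    attempts = _SURVIVAL_CAP if cfg.condition_on_survival else 1
    for _ in range(attempts):
        full = _simulate_once(cfg, rng)
        if full is None:
            if cfg.condition_on_survival:
                continue
            raise RuntimeError("lineage went extinct (condition_on_survival=False)")
        rec = _reconstructed(full)
        if rec is not None or not cfg.condition_on_survival:
            if rec is None:
                raise RuntimeError("fewer than 2 extant tips")
            return full, rec
    raise RuntimeError(
        "survival conditioning failed in 1e5 attempts; adjust rates or age")


def _node_ages(tree: dendropy.Tree) -> dict[int, float]:
    depth = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = 0.0
        else:
            depth[id(node)] = depth[id(node.parent_node)] + node.edge.length
    max_depth = max(depth[id(lf)] for lf in tree.leaf_node_iter())
    return {k: max_depth - v for k, v in depth.items()}


def collapse_to_richness_tree(
    tree: dendropy.Tree, collapse_age: float
) -> RichnessTree:
    """Collapse an ultrametric extant-only tree at ``collapse_age``.

    Every maximal clade whose stem branch crosses the collapse age becomes a
    terminal carrying its extant richness; stem ages are preserved and total
    richness equals the original tip count.
    """
    ages = _node_ages(tree)
    root_age = max(ages.values())
    if not 0 < collapse_age < root_age:
        raise ValueError(
            f"collapse_age must lie in (0, root_age={root_age:g})")
    work = tree.clone(depth=1)
    work_ages = _node_ages(work)
    richness: dict[str, int] = {}
    counter = 0
    for node in list(work.preorder_node_iter()):
        if node.parent_node is None:
            continue
        parent_age = work_ages[id(node.parent_node)]
        node_age = work_ages[id(node)]
        if parent_age > collapse_age >= node_age:
            counter += 1
            label = f"C{counter}"
            n_extant = len(node.leaf_nodes()) if not node.is_leaf() else 1
            node.clear_child_nodes()
            node.taxon = work.taxon_namespace.new_taxon(label)
            node.edge.length = parent_age  # tip sits at the present
            richness[label] = n_extant
    work.purge_taxon_namespace()
    newick = work.as_string(schema="newick", suppress_rooting=True)
    return richness_tree_from_newick(newick, richness)


def generate_richness_tree(
    n_tips: int,
    r: float,
    eps: float = 0.0,
    root_age: float = 100.0,
    seed: int = 0,
    shift_tips: int | None = None,
    r_shift: float | None = None,
    eps_shift: float | None = None,
    backbone_lambda: float = 0.05,
) -> tuple[RichnessTree, tuple[str, ...] | None]:
    """Richness tree with known generating rates, for parameter recovery.

    A pure-birth backbone with ``n_tips`` terminal clades is simulated and
    rescaled to ``root_age``; each terminal clade's richness is then drawn
    from the survival-conditioned birth-death clade-size law at its stem age
    — geometric with beta = (e^{rt}-1)/(e^{rt}-eps), the same law the
    taxonomic likelihood assumes.  If ``shift_tips`` is given, the internal
    edge whose clade size is closest to it (preferring deeper stems on ties)
    becomes a rate shift: tips below it use (``r_shift``, ``eps_shift``).

    Returns (tree, sorted tip labels of the true shift clade or None).
    """
    from sisterdiv.core_io import scale_root_height

    rng = np.random.default_rng(seed)
    cfg = BDSimConfig(lambda1=backbone_lambda, mu1=0.0,
                      n_tips_target=n_tips,
                      seed=int(rng.integers(2 ** 31)))
    _, rec = simulate_bd_tree(cfg)
    rt = richness_tree_from_newick(
        rec.as_string(schema="newick", suppress_rooting=True),
        {lf.taxon.label: 1 for lf in rec.leaf_node_iter()})
    rt = scale_root_height(rt, root_age)

    shift_set: frozenset | None = None
    if shift_tips is not None:
        if r_shift is None:
            raise ValueError("shift_tips requires r_shift")
        all_tips = frozenset(rt.tip_labels)
        best = None
        for node in rt.tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            tips = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if tips == all_tips:
                continue
            stem = rt.node_age(node.parent_node)
            key = (abs(len(tips) - shift_tips), -stem)
            if best is None or key < best[0]:
                best = (key, tips)
        if best is None:
            raise ValueError("no internal edge available for a shift")
        shift_set = best[1]

    richness = {}
    for label, _, t in rt.clades():
        if shift_set is not None and label in shift_set:
            rr = r_shift
            ee = eps if eps_shift is None else eps_shift
        else:
            rr, ee = r, eps
        ert = math.exp(rr * t)
        beta = (ert - 1.0) / (ert - ee)
        richness[label] = int(rng.geometric(1.0 - beta)) if beta > 0 else 1
    out = RichnessTree(
        tree=rt.tree, richness=richness, root_age=rt.root_age,
        has_polytomies=rt.has_polytomies, _node_age=rt._node_age)
    return out, (tuple(sorted(shift_set)) if shift_set is not None else None)
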
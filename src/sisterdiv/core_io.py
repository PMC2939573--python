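"""Data model and I/O: sister-pair tables and richness-annotated ultrametric trees.

A *sister pair* is one matched comparison between a gall-inducing clade and
its non-galling sister: extant described species counts plus host breadth,
the latter quantified as the age (Ma) of the most recent common ancestor of
each clade's host plants.  A *richness tree* is an ultrametric backbone tree
whose terminal nodes stand for collapsed clades carrying extant species
richness; it is the input to the taxonomic birth-death likelihood.

Richness is carried in a sidecar CSV (``tip_label,richness``) because no
Newick standard exists for richness annotation; a fallback ``label|count``
encoding inside tip labels is also accepted.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import pandas as pd

__all__ = [
    "SisterPair", "SisterPairTable", "RichnessTree", "ValidationError",
    "read_sister_table", "write_sister_table", "read_richness_tree",
    "write_richness_tree", "richness_tree_from_newick", "scale_root_height",
    "branching_times", "packaged_table1_path",
]

#: relative ultrametricity tolerance, as a fraction of root age
DEFAULT_ULTRAMETRIC_RTOL = 1e-6

_TABLE_COLUMNS = [
    "pair_id", "galler_name", "n_galler", "host_age_galler",
    "nongaller_name", "n_nongaller", "host_age_nongaller",
]


class ValidationError(ValueError):
    """Raised when an input file violates the data contract."""


@dataclass(frozen=True)
class SisterPair:
    """One galler / non-galler sister comparison.

    ``host_age_*`` is the host-MRCA age in Ma; 0 encodes hosts confined to a
    single terminal host lineage (no resolvable MRCA depth).  ``footnote_*``
    flags an asterisked age in the source table.
    """

    pair_id: str
    galler_name: str
    n_galler: int
    host_age_galler: float
    nongaller_name: str
    n_nongaller: int
    host_age_nongaller: float
    footnote_galler: bool = False
    footnote_nongaller: bool = False

    def __post_init__(self) -> None:
        if self.n_galler < 1 or self.n_nongaller < 1:
            raise ValidationError(
                f"pair {self.pair_id!r}: species counts must be >= 1 "
                f"(got {self.n_galler}, {self.n_nongaller})"
            )
        if self.host_age_galler < 0 or self.host_age_nongaller < 0:
            raise ValidationError(
                f"pair {self.pair_id!r}: host-MRCA ages must be >= 0"
            )

    @property
    def n_total(self) -> int:
        return self.n_galler + self.n_nongaller


@dataclass(frozen=True)
class SisterPairTable:
    """Ordered collection of sister pairs with unique ids."""

    pairs: tuple[SisterPair, ...]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValidationError("sister-pair table must contain at least one pair")
        ids = [p.pair_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate pair_id(s): {dup}")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[SisterPair]:
        return iter(self.pairs)

    def __getitem__(self, key: int | str) -> SisterPair:
        if isinstance(key, str):
            for p in self.pairs:
                if p.pair_id == key:
                    return p
            raise KeyError(key)
        return self.pairs[key]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for p in self.pairs:
            rows.append({
                "pair_id": p.pair_id,
                "galler_name": p.galler_name,
                "n_galler": p.n_galler,
                "host_age_galler": _format_age(p.host_age_galler, p.footnote_galler),
                "nongaller_name": p.nongaller_name,
                "n_nongaller": p.n_nongaller,
                "host_age_nongaller": _format_age(
                    p.host_age_nongaller, p.footnote_nongaller),
            })
        return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def _format_age(age: float, footnote: bool) -> str:
    s = f"{age:g}"
    return s + "*" if footnote else s


def _parse_age(raw: object, row: int, col: str) -> tuple[float, bool]:
    s = str(raw).strip()
    footnote = s.endswith("*")
    if footnote:
        s = s[:-1].strip()
    try:
        age = float(s)
    except ValueError:
        raise ValidationError(f"row {row}, column {col!r}: not a number: {raw!r}")
    if age < 0:
        raise ValidationError(f"row {row}, column {col!r}: negative age {age}")
    return age, footnote


def _parse_count(raw: object, row: int, col: str) -> int:
    try:
        f = float(raw)
    except (TypeError, ValueError):
        raise ValidationError(f"row {row}, column {col!r}: not an integer: {raw!r}")
    if f != int(f):
        raise ValidationError(f"row {row}, column {col!r}: non-integer count {raw!r}")
    return int(f)


def read_sister_table(path: str | Path) -> SisterPairTable:
    """Read a sister-pair CSV, validating every row.

    Required columns: ``pair_id, galler_name, n_galler, host_age_galler,
    nongaller_name, n_nongaller, host_age_nongaller``.  Extra columns (host
    taxon names, printed reference values) are ignored here and preserved by
    consumers that want them.  Ages may carry a trailing ``*`` footnote
    marker, which is stored as a flag.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    pairs = []
    for i, rec in enumerate(df.to_dict("records")):
        age_g, fn_g = _parse_age(rec["host_age_galler"], i, "host_age_galler")
        age_n, fn_n = _parse_age(rec["host_age_nongaller"], i, "host_age_nongaller")
        pairs.append(SisterPair(
            pair_id=str(rec["pair_id"]).strip(),
            galler_name=str(rec["galler_name"]).strip(),
            n_galler=_parse_count(rec["n_galler"], i, "n_galler"),
            host_age_galler=age_g,
            nongaller_name=str(rec["nongaller_name"]).strip(),
            n_nongaller=_parse_count(rec["n_nongaller"], i, "n_nongaller"),
            host_age_nongaller=age_n,
            footnote_galler=fn_g,
            footnote_nongaller=fn_n,
        ))
    return SisterPairTable(tuple(pairs))


def write_sister_table(table: SisterPairTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, index=False)


def packaged_table1_path() -> Path:
    """Path of the packaged galler/non-galler sister-comparison table."""
    return Path(importlib.resources.files("sisterdiv").joinpath("data/table1.csv"))


# ---------------------------------------------------------------------------
# richness trees


@dataclass(frozen=True)
class RichnessTree:
    """Ultrametric tree whose tips carry extant species richness.

    Node ages are measured backward from the present (tips at age 0).  The
    stem age of a tip is the age of its parent node; together with the tip's
    richness it is the sufficient statistic of the taxonomic birth-death
    likelihood.
    """

    tree: dendropy.Tree
    richness: Mapping[str, int]
    root_age: float
    has_polytomies: bool = False
    _node_age: Mapping[int, float] = field(default=None, repr=False, compare=False)

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return tuple(lf.taxon.label for lf in self.tree.leaf_node_iter())

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    @property
    def total_richness(self) -> int:
        return sum(self.richness[l] for l in self.tip_labels)

    def node_age(self, node: dendropy.Node) -> float:
        return self._node_age[id(node)]

    def stem_age(self, tip_label: str) -> float:
        """Age of the tip's parent node (root age for a root-child tip)."""
        for lf in self.tree.leaf_node_iter():
            if lf.taxon.label == tip_label:
                parent = lf.parent_node
                return self.root_age if parent is None else self.node_age(parent)
        raise KeyError(tip_label)

    def clades(self) -> list[tuple[str, int, float]]:
        """(tip label, richness, stem age) for every terminal clade."""
        out = []
        for lf in self.tree.leaf_node_iter():
            label = lf.taxon.label
            parent = lf.parent_node
            t = self.root_age if parent is None else self.node_age(parent)
            out.append((label, self.richness[label], t))
        return out

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def _build_richness_tree(
    tree: dendropy.Tree,
    richness: Mapping[str, int],
    rtol: float,
    source: str = "tree",
) -> RichnessTree:
    leaves = tree.leaf_nodes()
    labels = [lf.taxon.label for lf in leaves]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"{source}: duplicate tip labels")
    unknown = set(richness) - set(labels)
    if unknown:
        raise ValidationError(
            f"{source}: richness map has unknown tip(s): {sorted(unknown)}")
    missing = [l for l in labels if l not in richness]
    if missing:
        raise ValidationError(f"{source}: tips missing richness: {missing}")
    for l in labels:
        n = richness[l]
        if not (isinstance(n, (int,)) and n >= 1):
            raise ValidationError(f"{source}: tip {l!r}: richness must be int >= 1")

    depth: dict[int, float] = {}
    has_polytomies = False
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = 0.0
        else:
            elen = node.edge.length
            if elen is None or elen < 0:
                raise ValidationError(
                    f"{source}: every branch needs a non-negative length")
            depth[id(node)] = depth[id(node.parent_node)] + elen
        if not node.is_leaf() and len(node.child_nodes()) > 2:
            has_polytomies = True
        if not node.is_leaf() and len(node.child_nodes()) == 1:
            raise ValidationError(f"{source}: unifurcation in tree")

    tip_depths = [depth[id(lf)] for lf in leaves]
    root_age = max(tip_depths)
    if root_age <= 0:
        raise ValidationError(f"{source}: tree has zero depth")
    deviation = root_age - min(tip_depths)
    if deviation > rtol * root_age:
        raise ValidationError(
            f"{source}: tree is not ultrametric; max root-to-tip deviation "
            f"{deviation:g} exceeds tolerance {rtol * root_age:g}")

    node_age = {nid: root_age - d for nid, d in depth.items()}
    for lf in leaves:  # tips sit exactly at the present
        node_age[id(lf)] = 0.0
    return RichnessTree(
        tree=tree,
        richness=dict(richness),
        root_age=root_age,
        has_polytomies=has_polytomies,
        _node_age=node_age,
    )


def richness_tree_from_newick(
    newick: str,
    richness: Mapping[str, int] | None = None,
    rtol: float = DEFAULT_ULTRAMETRIC_RTOL,
) -> RichnessTree:
    """Build a RichnessTree from a Newick string.

    If ``richness`` is None, tip labels must use the ``label|count`` fallback
    encoding.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    if richness is None:
        richness = {}
        for lf in tree.leaf_node_iter():
            label = lf.taxon.label
            if "|" not in label:
                raise ValidationError(
                    f"tip {label!r}: no richness map given and label is not "
                    f"'name|count' encoded")
            name, _, count = label.rpartition("|")
            lf.taxon.label = name
            richness[name] = _parse_count(count, -1, "tip label")
    return _build_richness_tree(tree, richness, rtol)


def read_richness_tree(
    tree_path: str | Path,
    richness_path: str | Path | None = None,
    rtol: float = DEFAULT_ULTRAMETRIC_RTOL,
) -> RichnessTree:
    """Read a Newick tree plus a sidecar richness CSV (``tip_label,richness``).

    Without a sidecar, tip labels must encode richness as ``label|count``.
    """
    newick = Path(tree_path).read_text()
    richness = None
    if richness_path is not None:
        df = pd.read_csv(richness_path, dtype=str, skipinitialspace=True)
        need = {"tip_label", "richness"}
        if not need.issubset(df.columns):
            raise ValidationError(
                f"{richness_path}: need columns {sorted(need)}")
        richness = {
            str(r["tip_label"]).strip(): _parse_count(r["richness"], i, "richness")
            for i, r in enumerate(df.to_dict("records"))
        }
    return richness_tree_from_newick(newick, richness, rtol)


def write_richness_tree(
    rt: RichnessTree, tree_path: str | Path, richness_path: str | Path
) -> None:
    Path(tree_path).write_text(rt.as_newick() + "\n")
    pd.DataFrame(
        {"tip_label": list(rt.tip_labels),
         "richness": [rt.richness[l] for l in rt.tip_labels]}
    ).to_csv(richness_path, index=False)


def scale_root_height(rt: RichnessTree, target: float) -> RichnessTree:
    """Rescale all branch lengths so the root age equals ``target``.

    Only relative node heights carry information after nonparametric rate
    smoothing, so an arbitrary root height (conventionally 100) can be fixed.
    """
    if target <= 0:
        raise ValueError("target root height must be > 0")
    factor = target / rt.root_age
    clone = rt.tree.clone(depth=1)
    for edge in clone.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * factor
    return _build_richness_tree(clone, dict(rt.richness),
                                rtol=DEFAULT_ULTRAMETRIC_RTOL)


def branching_times(rt: RichnessTree) -> list[float]:
    """Internal-node ages, sorted descending (first entry = root age)."""
    ages = [rt.node_age(nd) for nd in rt.tree.preorder_node_iter()
            if not nd.is_leaf()]
    return sorted(ages, reverse=True)
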
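"""Alpha- and beta-diversity metrics, including phylogenetic weighted UniFrac.

Alpha metrics (functions of one composition): Shannon entropy, the
Gini-Simpson index ``1 - sum(p^2)``, the Gini inequality coefficient, and
the Aitchison norm (Euclidean norm of the clr vector).  Beta metrics
(functions of a pair): Bray-Curtis dissimilarity, weighted UniFrac on a
rooted tree, and the Aitchison distance (Euclidean distance between clr
vectors).  Natural logarithms throughout.

Weighted UniFrac accumulates descendant relative-abundance mass per edge in
a single post-order pass over a pre-indexed tree (:class:`TreeIndex`), so a
distance costs O(#edges) after one traversal.  The normalized variant
(default) divides the edge sum by ``sum_tips depth_tip * (p_tip + q_tip)``,
bounding it in [0, 1].

Only the Aitchison distance is perturbation invariant — it is unchanged
when both compositions receive the same log-ratio shift, which is exactly
how common PCR bias acts.  Bray-Curtis and weighted UniFrac are not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from io import StringIO

import dendropy
import numpy as np

from .compositions import as_composition, clr

__all__ = [
    "ALPHA_METRICS",
    "BETA_METRICS",
    "DistanceMatrix",
    "MetricSpec",
    "TreeIndex",
    "alpha_diversity",
    "beta_diversity",
    "distance_matrix",
    "read_newick",
    "write_newick",
]

ALPHA_METRICS = ("shannon", "simpson", "gini", "aitchison_norm")
BETA_METRICS = ("bray_curtis", "weighted_unifrac", "aitchison_distance")


@dataclass(frozen=True)
class MetricSpec:
    """A named diversity metric plus metric-specific options.

    Options: ``normalized`` (bool, weighted UniFrac only; default True).
    """

    name: str
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in ALPHA_METRICS + BETA_METRICS:
            raise ValueError(
                f"unknown metric {self.name!r}; alpha: {ALPHA_METRICS}, beta: {BETA_METRICS}"
            )
        unknown = set(self.options) - {"normalized"}
        if unknown:
            raise ValueError(f"unknown options for {self.name}: {sorted(unknown)}")

    @property
    def is_alpha(self) -> bool:
        return self.name in ALPHA_METRICS


def _as_metric(metric) -> MetricSpec:
    if isinstance(metric, MetricSpec):
        return metric
    return MetricSpec(str(metric))


def _shannon(p: np.ndarray) -> float:
    return float(-(p * np.log(p)).sum())


def _simpson(p: np.ndarray) -> float:
    return float(1.0 - (p**2).sum())


def _gini(p: np.ndarray) -> float:
    d = p.size
    return float(np.abs(p[:, None] - p[None, :]).sum() / (2.0 * d))


def _aitchison_norm(p: np.ndarray) -> float:
    return float(np.linalg.norm(clr(p)))


_ALPHA_FUNCS = {
    "shannon": _shannon,
    "simpson": _simpson,
    "gini": _gini,
    "aitchison_norm": _aitchison_norm,
}


def alpha_diversity(c, metric) -> float:
    """Evaluate an alpha-diversity metric on one composition."""
    spec = _as_metric(metric)
    if not spec.is_alpha:
        raise ValueError(f"{spec.name!r} is a beta metric; use beta_diversity")
    return _ALPHA_FUNCS[spec.name](as_composition(c))


class TreeIndex:
    """Post-order index of a rooted tree for fast repeated UniFrac calls.

    ``taxon_order`` fixes the mapping between composition entries and tips;
    it must be exactly the tree's tip label set.
    """

    def __init__(self, tree: dendropy.Tree, taxon_order: list[str] | None = None):
        nodes = list(tree.postorder_node_iter())
        tip_labels = [nd.taxon.label for nd in nodes if nd.is_leaf()]
        if len(set(tip_labels)) != len(tip_labels):
            raise ValueError("tree has duplicate tip labels")
        if taxon_order is None:
            taxon_order = sorted(tip_labels)
        if set(taxon_order) != set(tip_labels) or len(taxon_order) != len(tip_labels):
            raise ValueError("taxon_order must match the tree's tip labels exactly")
        self.taxon_order = list(taxon_order)
        pos = {lab: i for i, lab in enumerate(self.taxon_order)}

        index = {id(nd): i for i, nd in enumerate(nodes)}
        n_nodes = len(nodes)
        self.n_nodes = n_nodes
        self.root_index = n_nodes - 1  # post-order puts the root last
        self.edge_lengths = np.zeros(n_nodes)
        self.tip_slot = np.full(n_nodes, -1, dtype=int)  # composition index per tip node
        self.children: list[list[int]] = [[] for _ in range(n_nodes)]
        for i, nd in enumerate(nodes):
            if nd.edge.length is not None:
                self.edge_lengths[i] = float(nd.edge.length)
            if nd.is_leaf():
                self.tip_slot[i] = pos[nd.taxon.label]
            for ch in nd.child_nodes():
                self.children[i].append(index[id(ch)])
        if np.any(self.edge_lengths < 0):
            raise ValueError("branch lengths must be nonnegative")
        # root-to-tip distances, ordered like taxon_order
        depth = np.zeros(n_nodes)
        for i in reversed(range(n_nodes)):  # pre-order
            for ch in self.children[i]:
                depth[ch] = depth[i] + self.edge_lengths[ch]
        self.tip_depths = np.zeros(len(self.taxon_order))
        for i in range(n_nodes):
            if self.tip_slot[i] >= 0:
                self.tip_depths[self.tip_slot[i]] = depth[i]

    def node_masses(self, p: np.ndarray) -> np.ndarray:
        """Total descendant relative abundance under each node (post-order)."""
        m = np.zeros(self.n_nodes)
        for i in range(self.n_nodes):
            if self.tip_slot[i] >= 0:
                m[i] = p[self.tip_slot[i]]
            else:
                for ch in self.children[i]:
                    m[i] += m[ch]
        return m

    def weighted_unifrac(self, p: np.ndarray, q: np.ndarray, normalized: bool = True) -> float:
        mp = self.node_masses(p)
        mq = self.node_masses(q)
        raw = float((self.edge_lengths * np.abs(mp - mq)).sum())  # root edge length is 0
        if not normalized:
            return raw
        denom = float((self.tip_depths * (p + q)).sum())
        if denom <= 0:
            raise ValueError("tree has zero total root-to-tip depth; cannot normalize")
        return raw / denom


def _resolve_tree(tree, taxon_ids, D: int) -> TreeIndex:
    if tree is None:
        raise ValueError("weighted_unifrac requires a phylogenetic tree")
    if isinstance(tree, TreeIndex):
        idx = tree
        if taxon_ids is not None and list(taxon_ids) != idx.taxon_order:
            raise ValueError("taxon_ids disagree with the TreeIndex taxon order")
    else:
        idx = TreeIndex(tree, list(taxon_ids) if taxon_ids is not None else None)
    if len(idx.taxon_order) != D:
        raise ValueError(
            f"tree has {len(idx.taxon_order)} tips but compositions have {D} parts"
        )
    return idx


def beta_diversity(c1, c2, metric, tree=None, taxon_ids=None) -> float:
    """Evaluate a beta-diversity metric on a pair of compositions.

    For ``weighted_unifrac`` a rooted ``tree`` (dendropy Tree or
    :class:`TreeIndex`) is required; ``taxon_ids`` gives the tip label for
    each composition entry (default: tips sorted by label).
    """
    spec = _as_metric(metric)
    if spec.is_alpha:
        raise ValueError(f"{spec.name!r} is an alpha metric; use alpha_diversity")
    p = as_composition(c1)
    q = as_composition(c2)
    if p.size != q.size:
        raise ValueError("compositions must share the same taxa")
    if spec.name == "bray_curtis":
        return float(0.5 * np.abs(p - q).sum())
    if spec.name == "aitchison_distance":
        return float(np.linalg.norm(clr(p) - clr(q)))
    idx = _resolve_tree(tree, taxon_ids, p.size)
    return idx.weighted_unifrac(p, q, normalized=bool(spec.options.get("normalized", True)))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise-distance matrix with a zero diagonal."""

    entries: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        d = np.asarray(self.entries, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if np.max(np.abs(d - d.T)) > 1e-12:
            raise ValueError("distance matrix must be symmetric")
        if np.max(np.abs(np.diag(d))) > 1e-12:
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(d < 0):
            raise ValueError("distances must be nonnegative")
        if len(self.sample_ids) != d.shape[0]:
            raise ValueError("sample_ids length must match the matrix")
        self.entries = (d + d.T) / 2
        np.fill_diagonal(self.entries, 0.0)
        self.sample_ids = list(self.sample_ids)

    @property
    def N(self) -> int:
        return self.entries.shape[0]


def distance_matrix(comps, metric, tree=None, taxon_ids=None, sample_ids=None) -> DistanceMatrix:
    """Assemble all pairwise beta diversities into a :class:`DistanceMatrix`."""
    comps = [as_composition(c) for c in comps]
    if len(comps) < 2:
        raise ValueError("need at least 2 compositions")
    spec = _as_metric(metric)
    if spec.name == "weighted_unifrac":
        tree = _resolve_tree(tree, taxon_ids, comps[0].size)
        taxon_ids = None  # already baked into the index
    n = len(comps)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = beta_diversity(comps[i], comps[j], spec, tree, taxon_ids)
    ids = list(sample_ids) if sample_ids is not None else [f"sample_{i + 1:03d}" for i in range(n)]
    return DistanceMatrix(d, ids)


def read_newick(path_or_string) -> dendropy.Tree:
    """Read a rooted tree from a Newick file path (or literal Newick string).

    Missing branch lengths are set to zero with a warning; duplicate tip
    labels are rejected.
    """
    s = str(path_or_string)
    try:
        if s.lstrip().startswith("("):
            tree = dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)
        else:
            tree = dendropy.Tree.get(path=s, schema="newick", preserve_underscores=True)
    except Exception as exc:
        raise ValueError(f"failed to parse Newick input: {exc}") from exc
    tree.is_rooted = True
    tips = [nd.taxon.label for nd in tree.leaf_node_iter()]
    if len(tips) < 2:
        raise ValueError("tree must have at least 2 tips")
    if len(set(tips)) != len(tips):
        raise ValueError("tree has duplicate tip labels")
    missing = 0
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None and nd.edge.length is None:
            nd.edge.length = 0.0
            missing += 1
    if missing:
        warnings.warn(f"{missing} branch length(s) missing; set to 0", stacklevel=2)
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True, unquoted_underscores=True)
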
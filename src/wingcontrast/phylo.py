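"""Phylogenies: Newick I/O, Brownian covariance matrices, Pagel's lambda,
and a seeded Yule simulator for synthetic tree sets.

Under Brownian evolution on a rooted tree, the expected covariance of a
trait between two tips equals the shared root-to-tip path length of those
tips; the tip-by-tip matrix of shared path lengths (the "VCV") is therefore
the relatedness structure used as the phylogenetic random effect. Scaling
the tree to unit height makes variance components comparable across trees
of different depths. Pagel's lambda discounts the off-diagonal covariances
by a factor in [0, 1]: lambda = 1 keeps the Brownian structure, lambda = 0
erases shared history (a star phylogeny).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np


class NewickError(ValueError):
    """Malformed or unsupported Newick input."""


@dataclass
class Phylogeny:
    """Rooted tree with unique tip labels and branch lengths >= 0."""

    tree: dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def tip_depths(self) -> np.ndarray:
        depths = []
        for leaf in self.tree.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length
                node = node.parent_node
            depths.append(d)
        return np.asarray(depths)

    def height(self) -> float:
        return float(self.tip_depths().max())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = self.tip_depths()
        return bool(np.ptp(d) <= rel_tol * d.max())


@dataclass
class PhyloCovariance:
    """Tip-ordered shared-path-length matrix (PSD, symmetric)."""

    labels: list[str]
    matrix: np.ndarray
    scaled: bool

    @property
    def n(self) -> int:
        return len(self.labels)

    def reorder(self, labels: list[str]) -> "PhyloCovariance":
        """Reindex rows/columns to a label order; a subset of the tips prunes
        the matrix (valid for ultrametric trees, where dropping tips leaves
        the remaining shared path lengths unchanged)."""
        pos = {lab: i for i, lab in enumerate(self.labels)}
        missing = [lab for lab in labels if lab not in pos]
        if missing:
            raise ValueError(f"label mismatch with covariance matrix: {missing[:5]}")
        idx = np.array([pos[lab] for lab in labels])
        return PhyloCovariance(list(labels), self.matrix[np.ix_(idx, idx)], self.scaled)


def read_newick(text: str) -> Phylogeny:
    """Parse one rooted Newick tree; branch lengths required on non-root edges."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick", suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickError(f"malformed Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon is not None]
    if len(labels) != len(set(labels)):
        raise NewickError("duplicate tip labels")
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            raise NewickError("missing branch length")
        if node.edge.length < 0:
            raise NewickError("negative branch length")
    return Phylogeny(tree)


def write_newick(phy: Phylogeny) -> str:
    return phy.tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_tree_set(path) -> list[Phylogeny]:
    """Read a file with one Newick tree per line."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(read_newick(line))
    return trees


def write_tree_set(trees: list[Phylogeny], path) -> None:
    with open(path, "w") as fh:
        for phy in trees:
            fh.write(write_newick(phy) + "\n")


def prune_to(phy: Phylogeny, labels) -> Phylogeny:
    """Prune the tree to the given tip labels (all must be present)."""
    keep = set(labels)
    have = set(phy.tip_labels)
    missing = sorted(keep - have)
    if missing:
        raise ValueError(f"labels absent from tree: {missing[:5]}")
    tree = phy.tree.clone(depth=1)
    tree.retain_taxa_with_labels(sorted(keep))
    return Phylogeny(tree)


def vcv_from_tree(phy: Phylogeny, scale: bool = True) -> PhyloCovariance:
    """Shared root-to-tip path lengths: V[i, j] = depth of MRCA(i, j).

    With ``scale=True`` the matrix is divided by the maximum tip depth, so an
    ultrametric tree gets a unit diagonal. Built edge-by-edge: each edge of
    length L adds L to every pair of tips descending from it, which handles
    polytomies without special cases.
    """
    leaves = list(phy.tree.leaf_node_iter())
    labels = [leaf.taxon.label for leaf in leaves]
    index = {id(leaf): i for i, leaf in enumerate(leaves)}
    n = len(leaves)
    V = np.zeros((n, n))
    for node in phy.tree.postorder_node_iter():
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            raise NewickError("missing branch length")
        if node.edge.length < 0:
            raise NewickError("negative branch length")
        idx = np.array([index[id(leaf)] for leaf in node.leaf_iter()])
        V[np.ix_(idx, idx)] += node.edge.length
    if scale:
        V = V / V.diagonal().max()
    return PhyloCovariance(labels, V, scaled=scale)


def lambda_transform(vcv: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Multiply off-diagonal covariances by lambda, keep the diagonal.

    Composition multiplies: transforming by l1 then l2 equals l1 * l2.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    V = vcv.matrix * lam
    np.fill_diagonal(V, vcv.matrix.diagonal())
    return PhyloCovariance(list(vcv.labels), V, vcv.scaled)


def simulate_yule(
    n_tips: int,
    birth_rate: float = 1.0,
    seed: int | np.random.Generator = 0,
    prefix: str = "sp",
) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree with exactly ``n_tips`` tips.

    Starting from the root's two daughter lineages, each lineage splits at
    rate ``birth_rate``; waiting times between splits are Exp(k * birth_rate)
    with k extant lineages. After the (n-1)-th split a final Exp(n * rate)
    stretch is added so terminal branches have positive length. Expected root
    height is sum_{k=2..n} 1/(k * rate). Deterministic under a fixed seed.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # each active lineage: [start_time, node]; node = [children] or None for a tip
    nodes: dict[int, dict] = {}
    counter = 0

    def new_node(start):
        nonlocal counter
        counter += 1
        nodes[counter] = {"start": start, "children": []}
        return counter

    root = new_node(0.0)
    active = [new_node(0.0), new_node(0.0)]
    nodes[root]["children"] = list(active)
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        i = int(rng.integers(k))
        parent = active.pop(i)
        nodes[parent]["end"] = t
        kids = [new_node(t), new_node(t)]
        nodes[parent]["children"] = kids
        active.extend(kids)
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    for nid in active:
        nodes[nid]["end"] = t

    width = len(str(n_tips))
    tip_counter = [0]

    def render(nid: int, is_root: bool) -> str:
        node = nodes[nid]
        if node["children"]:
            inner = ",".join(render(c, False) for c in node["children"])
            label = f"({inner})"
        else:
            tip_counter[0] += 1
            label = f"{prefix}{tip_counter[0]:0{width}d}"
        if is_root:
            return f"{label};"
        return f"{label}:{node['end'] - node['start']:.12f}"

    return read_newick(render(root, True))
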
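"""Neighbor-joining trees with column-bootstrap support values.

NJ is the classic agglomerative distance method: at each step the pair (i, j)
minimising

    Q(i, j) = (r - 2) d(i, j) - R_i - R_j,     R_i = Σ_k d(i, k)

over the r active nodes is joined, branch lengths follow the standard
formulas, and distances to the new node are d(u, k) = (d(i,k)+d(j,k)-d(i,j))/2.
On an additive distance matrix this recovers the generating tree exactly
(path lengths on the output tree reproduce the input matrix).

Determinism contract: ties in the Q minimisation are broken by the lowest
(row, col) index pair in the current canonical ordering (input order, new
nodes appended), so a permutation of the input taxa yields the same unrooted
topology.  Negative branch lengths are clamped to zero with the deficit moved
to the sister edge, keeping the joined pair's path length intact.

Support values come from resampling alignment columns with replacement,
rebuilding the tree per replicate, and counting how often each internal-edge
bipartition of the main tree recurs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from ._errors import InputError, NewickParseError
from .distances import GapPolicy, PDistanceMatrix, distance_matrix
from .seqio import AnnotatedSequence

logger = logging.getLogger(__name__)


@dataclass
class PhyloTree:
    """An unrooted tree with branch lengths and optional bootstrap supports.

    Wraps a :class:`dendropy.Tree`; supports live on internal-node labels
    (proportions in [0, 1]) and survive Newick round trips.
    """

    tree: dendropy.Tree
    dropped_replicates: int = 0

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(lf.taxon.label for lf in self.tree.leaf_node_iter())

    def newick(self) -> str:
        s = self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".10g",
        )
        return s.strip() + "\n"

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each as its canonical leaf-label side.

        The canonical side is the one containing the lexicographically
        smallest leaf label, so sets compare across trees over the same taxa.
        """
        all_leaves = set(self.leaf_labels)
        anchor = min(all_leaves)
        out: set[frozenset[str]] = set()
        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node or node.is_leaf():
                continue
            below = {lf.taxon.label for lf in node.leaf_iter()}
            above = all_leaves - below
            if len(below) >= 2 and len(above) >= 2:
                out.add(frozenset(below if anchor in below else above))
        return out

    def supports(self) -> dict[frozenset[str], float]:
        """Map canonical bipartition -> support, from internal-node labels."""
        all_leaves = set(self.leaf_labels)
        anchor = min(all_leaves)
        out: dict[frozenset[str], float] = {}
        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node or node.is_leaf():
                continue
            if node.label is None:
                continue
            below = {lf.taxon.label for lf in node.leaf_iter()}
            above = all_leaves - below
            if len(below) >= 2 and len(above) >= 2:
                key = frozenset(below if anchor in below else above)
                out[key] = float(node.label)
        return out

    def path_length_matrix(self, ids: Sequence[str]) -> np.ndarray:
        """Patristic (tree path-length) distances between the given leaves."""
        pdm = self.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self.tree.taxon_namespace}
        n = len(ids)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = pdm.patristic_distance(
                    taxa[ids[i]], taxa[ids[j]]
                )
        return out


# ---------------------------------------------------------------------------
# NJ core


def nj(matrix: PDistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree from a distance matrix.

    Requires every pair to be defined; an undefined (NaN) pair raises
    :class:`InputError` naming the offending accessions.
    """
    n = matrix.n
    if n < 2:
        raise InputError("nj needs at least 2 taxa")
    bad = matrix.flagged_pairs
    if bad:
        raise InputError(f"undefined distance for pair {bad[0][0]}--{bad[0][1]}")

    ns = dendropy.TaxonNamespace(matrix.ids)
    nodes: list[dendropy.Node] = []
    for acc in matrix.ids:
        node = dendropy.Node(taxon=ns.get_taxon(acc))
        nodes.append(node)
    d = matrix.p.astype(float).copy()

    def join(i: int, j: int, li: float, lj: float) -> dendropy.Node:
        # clamp-to-zero with the deficit shifted to the sister edge
        if li < 0:
            lj, li = li + lj, 0.0
        if lj < 0:
            li, lj = li + lj, 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = max(li, 0.0)
        parent.add_child(nodes[j])
        nodes[j].edge.length = max(lj, 0.0)
        return parent

    while len(nodes) > 3:
        r = d.shape[0]
        R = d.sum(axis=1)
        Q = (r - 2) * d - R[:, None] - R[None, :]
        # restrict to the upper triangle; argmin scans row-major, which is
        # exactly the lowest-(row, col) tie-break
        Q[np.tril_indices(r)] = np.inf
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)
        li = 0.5 * d[i, j] + (R[i] - R[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        parent = join(i, j, li, lj)
        du = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], du[keep]])
        d = np.hstack([d, np.append(du[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    root = dendropy.Node()
    if len(nodes) == 2:
        half = d[0, 1] / 2.0
        for k in range(2):
            root.add_child(nodes[k])
            nodes[k].edge.length = max(half, 0.0)
    else:
        la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
        lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
        lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
        for k, lk in zip(range(3), (la, lb, lc)):
            root.add_child(nodes[k])
            nodes[k].edge.length = max(lk, 0.0)

    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = False
    return PhyloTree(tree)


# ---------------------------------------------------------------------------
# Bootstrap


def _resample_columns(
    seqs: Sequence[AnnotatedSequence], cols: np.ndarray
) -> list[AnnotatedSequence]:
    return [
        AnnotatedSequence(
            s.accession, "".join(s.residues[c] for c in cols), s.lineage
        )
        for s in seqs
    ]


def bootstrap_supports(
    seqs: Sequence[AnnotatedSequence],
    b: int = 1000,
    seed: int = 0,
    policy: GapPolicy = "pairwise",
) -> PhyloTree:
    """NJ tree with bootstrap supports from column resampling.

    Resamples alignment columns with replacement ``b`` times, rebuilds the
    tree per replicate with the same gap policy, and writes onto each
    internal node of the main tree the fraction of retained replicates whose
    tree contains the same bipartition.  Replicates producing an undefined
    pair are dropped and counted in ``dropped_replicates``.  Fully
    reproducible for a fixed seed.
    """
    if b < 1:
        raise InputError("bootstrap needs b >= 1 replicates")
    main = nj(distance_matrix(seqs, policy))
    length = len(seqs[0])
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in main.bipartitions()}
    retained = 0
    dropped = 0
    for _ in range(b):
        cols = rng.integers(0, length, size=length)
        resampled = _resample_columns(seqs, cols)
        try:
            rep = nj(distance_matrix(resampled, policy))
        except InputError:
            dropped += 1
            continue
        retained += 1
        for bp in rep.bipartitions():
            if bp in counts:
                counts[bp] += 1
    if dropped:
        logger.warning("bootstrap: dropped %d/%d replicates", dropped, b)

    all_leaves = set(main.leaf_labels)
    anchor = min(all_leaves)
    for node in main.tree.preorder_node_iter():
        if node is main.tree.seed_node or node.is_leaf():
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        above = all_leaves - below
        if len(below) >= 2 and len(above) >= 2:
            key = frozenset(below if anchor in below else above)
            s = counts[key] / retained if retained else 0.0
            node.label = repr(s)
    main.dropped_replicates = dropped
    return main


# ---------------------------------------------------------------------------
# Newick I/O


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.newick())


def read_newick(path: str | Path) -> PhyloTree:
    try:
        t = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        pos = getattr(exc, "col_num", None)
        raise NewickParseError(f"malformed Newick in {path}: {exc}", pos) from exc
    t.is_rooted = False
    return PhyloTree(t)
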
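"""Gene-tree inference with support values.

Two routes produce the :class:`SupportTree` consumed by the clan scan:

* an internal distance pipeline — Jukes–Cantor distances on a nucleotide
  alignment, neighbor joining, and nonparametric bootstrap over alignment
  columns — which is self-contained and fully seeded; and
* an importer for externally built Newick trees whose internal node labels
  carry support values (fractions in [0,1] are normalised to percentages).

Leaf labels follow the "<species>_<locus>" convention: the species id is the
first delimiter-separated token of the label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "Alignment",
    "SupportTree",
    "jc_distance",
    "jc_distance_matrix",
    "nj",
    "bootstrap_support",
    "read_newick",
    "write_newick",
    "iter_bipartitions",
    "canonical_bipartition",
]

#: JC distance returned when the proportion of differing sites reaches the
#: model's saturation point p >= 3/4 (the log argument would be <= 0).
SATURATION_CEILING = 5.0

_VALID = frozenset(b"ACGT")


class Alignment:
    """An in-memory nucleotide alignment: gene_id -> equal-length row."""

    def __init__(self, rows: Mapping[str, str]):
        if len(rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        lengths = {len(s) for s in rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"alignment rows have unequal lengths: {sorted(lengths)}")
        self.rows: dict[str, str] = {k: v.upper() for k, v in rows.items()}
        self.length = lengths.pop()

    def labels(self) -> list[str]:
        return sorted(self.rows)

    def matrix(self) -> np.ndarray:
        """Rows as a (n, L) uint8 array in sorted-label order."""
        return np.frombuffer(
            "".join(self.rows[k] for k in self.labels()).encode(), dtype=np.uint8
        ).reshape(len(self.rows), self.length)


@dataclass
class SupportTree:
    """An (effectively unrooted) gene tree with per-edge support percentages.

    Wraps a dendropy tree; internal node labels hold integer supports in
    [0, 100] where available.  ``delimiter`` governs how leaf labels split
    into (species, locus).
    """

    tree: dendropy.Tree
    delimiter: str = "_"

    def species_of(self, leaf_label: str) -> str:
        return leaf_label.split(self.delimiter)[0]

    def leaf_labels(self) -> list[str]:
        return sorted(lf.taxon.label for lf in self.tree.leaf_node_iter())

    def leaves_by_species(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for label in self.leaf_labels():
            out.setdefault(self.species_of(label), set()).add(label)
        return out

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# Distances


def jc_distance(a: str, b: str, ceiling: float = SATURATION_CEILING) -> float:
    """Jukes–Cantor distance between two aligned rows.

    Sites with a gap or N in either row are excluded.  With p the
    proportion of differing comparable sites, d = -(3/4) ln(1 - 4p/3);
    p >= 3/4 returns the saturation ceiling.
    """
    if len(a) != len(b):
        raise ValueError("rows have different lengths")
    comparable = 0
    mismatches = 0
    for x, y in zip(a.upper().encode(), b.upper().encode()):
        if x in _VALID and y in _VALID:
            comparable += 1
            if x != y:
                mismatches += 1
    if comparable == 0:
        raise ValueError("no comparable sites between rows")
    p = mismatches / comparable
    if p >= 0.75:
        return ceiling
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def jc_distance_matrix(aln: Alignment, columns: np.ndarray | None = None,
                       ceiling: float = SATURATION_CEILING) -> tuple[np.ndarray, list[str]]:
    """Pairwise JC distance matrix (sorted-label order).

    ``columns`` optionally selects (with repetition) the alignment columns
    to use — the hook for bootstrap resampling.
    """
    labels = aln.labels()
    mat = aln.matrix()
    if columns is not None:
        mat = mat[:, columns]
    n = len(labels)
    valid = np.isin(mat, np.frombuffer(b"ACGT", dtype=np.uint8))
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            comparable = int(both.sum())
            if comparable == 0:
                raise ValueError(
                    f"no comparable sites between {labels[i]} and {labels[j]}"
                )
            p = int((mat[i][both] != mat[j][both]).sum()) / comparable
            if p >= 0.75:
                d = ceiling
            else:
                d = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
            D[i, j] = D[j, i] = d
    return D, labels


# ---------------------------------------------------------------------------
# Neighbor joining


def nj(D: np.ndarray, labels: Sequence[str],
       taxon_namespace: dendropy.TaxonNamespace | None = None) -> SupportTree:
    """Neighbor joining on a symmetric distance matrix.

    Standard agglomeration; negative branch-length estimates are clamped to
    zero.  The result is returned with a trifurcating seed node, i.e. an
    unrooted topology.  For n = 3 the unique star resolution with branch
    lengths from the three-point formulas is returned.
    """
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix is not symmetric")
    if not np.all(np.isfinite(D)):
        raise ValueError("distance matrix has non-finite entries")

    tns = taxon_namespace or dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for label in labels:
        node = dendropy.Node()
        node.taxon = tns.require_taxon(label=label)
        nodes.append(node)
    # keys give deterministic tie-breaking on the Q criterion
    keys: list[tuple] = [(label,) for label in labels]
    d = D.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        best_q = math.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12
                    and best is not None
                    and (keys[i], keys[j]) < (keys[best[0]], keys[best[1]])
                ):
                    best_q = q
                    best = (i, j)
        i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        parent = dendropy.Node()
        ni, nj_ = nodes[i], nodes[j]
        parent.add_child(ni)
        parent.add_child(nj_)
        ni.edge.length = max(0.0, li)
        nj_.edge.length = max(0.0, lj)
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], new_d[keep]])
        d = np.hstack([d, np.append(new_d[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    root = dendropy.Node()
    a, b, c = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    for node, length in ((a, la), (b, lb), (c, lc)):
        root.add_child(node)
        node.edge.length = max(0.0, length)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return SupportTree(tree)


# ---------------------------------------------------------------------------
# Bipartitions and bootstrap


def canonical_bipartition(side: frozenset, all_labels: frozenset) -> frozenset:
    """Canonical form of an unrooted bipartition: the half not containing
    the lexicographically smallest leaf label."""
    ref = min(all_labels)
    return frozenset(all_labels - side) if ref in side else frozenset(side)


def iter_bipartitions(stree: SupportTree):
    """Yield (side, node) for every internal edge of the unrooted tree.

    ``side`` is the frozenset of leaf labels below the edge's child node.
    Pendant edges are excluded; the redundant root-child edge of a
    bifurcating rooted representation is deduplicated.
    """
    tree = stree.tree
    all_labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    seen: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(side) < 2 or len(all_labels - side) < 2:
            continue  # trivial bipartition
        canon = canonical_bipartition(side, all_labels)
        if canon in seen:
            continue
        seen.add(canon)
        yield side, node


def bootstrap_support(aln: Alignment, n_reps: int = 500,
                      seed: int = 0) -> SupportTree:
    """Point-estimate NJ tree with bootstrap supports on internal edges.

    Columns are resampled with replacement ``n_reps`` times (seeded); each
    internal edge's support is the percentage of replicate trees containing
    its bipartition, rounded to the nearest integer and stored as the edge's
    child-node label.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    D, labels = jc_distance_matrix(aln)
    tns = dendropy.TaxonNamespace()
    point = nj(D, labels, taxon_namespace=tns)
    all_labels = frozenset(labels)

    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(n_reps):
        cols = rng.integers(0, aln.length, size=aln.length)
        Db, _ = jc_distance_matrix(aln, columns=cols)
        rep = nj(Db, labels, taxon_namespace=tns)
        for side, _node in iter_bipartitions(rep):
            canon = canonical_bipartition(side, all_labels)
            counts[canon] = counts.get(canon, 0) + 1

    for side, node in iter_bipartitions(point):
        canon = canonical_bipartition(side, all_labels)
        support = round(100.0 * counts.get(canon, 0) / n_reps)
        node.label = str(int(support))
    return point


# ---------------------------------------------------------------------------
# Newick I/O


def read_newick(path: str | Path, delimiter: str = "_") -> SupportTree:
    """Import a Newick gene tree with supports as internal node labels.

    Supports in [0, 1] are interpreted as fractions and scaled to
    percentages; every leaf label must contain the species/locus delimiter
    or consist of a bare species token.
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = False
    supports = []
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.label is None:
            continue
        try:
            supports.append(float(node.label))
        except ValueError:
            raise ValueError(f"unparseable support label {node.label!r}") from None
    scale = 100.0 if supports and max(supports) <= 1.0 else 1.0
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.label is None:
            continue
        node.label = str(int(round(float(node.label) * scale)))
    stree = SupportTree(tree, delimiter=delimiter)
    for label in stree.leaf_labels():
        if not label:
            raise ValueError("empty leaf label in Newick input")
    return stree


def write_newick(stree: SupportTree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(stree.as_newick() + "\n")
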
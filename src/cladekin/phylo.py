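"""Distance-based phylogeny with bootstrap support.

A neighbor-joining tree on p-distances or Poisson-corrected distances is
the desk-scale stand-in used here for full maximum-likelihood inference:
for the order-level clustering questions this package asks (are the
members of a taxonomic order monophyletic, with what bootstrap support),
NJ on corrected distances is adequate and exactly reconstructs any
additive distance matrix.  Trees are dendropy objects throughout, so
Newick I/O and downstream manipulation use the standard toolkit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

from .errors import DataError
from .seq_core import GAP_CHAR, Alignment, conserved_columns


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise DataError("distance matrix shape does not match taxa")
        if len(set(self.taxa)) != n:
            raise DataError("duplicate taxon labels")
        if not np.allclose(self.matrix, self.matrix.T):
            raise DataError("distance matrix is not symmetric")
        if np.any(np.diagonal(self.matrix) != 0):
            raise DataError("distance matrix diagonal must be zero")
        if np.any(self.matrix < 0) or not np.all(np.isfinite(self.matrix)):
            raise DataError("distances must be finite and non-negative")

    def to_tsv(self) -> str:
        lines = ["\t".join(["taxon", *self.taxa])]
        for t, row in zip(self.taxa, self.matrix):
            lines.append("\t".join([t, *(f"{x:.10g}" for x in row)]))
        return "\n".join(lines) + "\n"


def pairwise_distances(
    alignment: Alignment,
    columns: list[int] | None = None,
    model: str = "poisson",
) -> DistanceMatrix:
    """Pairwise distances over the given 1-based columns.

    model "p": mismatches / mutually ungapped compared columns;
    model "poisson": -ln(1 - p), the standard correction for multiple
    hits.  p = 1 has infinite Poisson distance and is rejected.
    """
    if model not in ("p", "poisson"):
        raise DataError(f"unknown distance model {model!r}")
    if columns is None:
        columns = conserved_columns(alignment)
    if not columns:
        raise DataError("no columns to compute distances over")
    idx = np.array([c - 1 for c in columns])
    chars = np.array([list(s.residues) for s in alignment.sequences])[:, idx]
    ungapped = chars != GAP_CHAR
    n = len(alignment.sequences)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ungapped[i] & ungapped[j]
            m = int(both.sum())
            if m == 0:
                raise DataError(
                    f"sequences {alignment.ids[i]!r} and {alignment.ids[j]!r} share "
                    "no ungapped columns; choose columns with fewer gaps"
                )
            p = float((chars[i][both] != chars[j][both]).sum()) / m
            if model == "poisson":
                if p >= 1.0:
                    raise DataError(
                        f"saturated pair {alignment.ids[i]!r}/{alignment.ids[j]!r} "
                        "(p = 1): Poisson distance is infinite; use model='p' or "
                        "restrict to more conserved columns"
                    )
                p = -math.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(taxa=list(alignment.ids), matrix=d)


def _clamp(length: float, sibling: float) -> tuple[float, float]:
    # negative NJ branch: clamp to 0, move the deficit to the sibling edge
    if length < 0:
        sibling += length
        length = 0.0
    return length, max(sibling, 0.0)


def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; exact on additive matrices.

    Returns an unrooted dendropy tree (trifurcating seed node).  Negative
    branch lengths are clamped to zero with the deficit moved to the
    sibling edge; ties in the Q criterion break toward the lexically
    first taxon pair for determinism.
    """
    n = len(D.taxa)
    if n < 3:
        raise DataError("neighbor joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace(D.taxa)
    nodes: list[dendropy.Node] = []
    for label in D.taxa:
        node = dendropy.Node(taxon=tns.get_taxon(label))
        nodes.append(node)
    d = D.matrix.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_s, j_s = np.unravel_index(np.argmin(q), q.shape)  # row-major: deterministic
        if i_s > j_s:
            i_s, j_s = j_s, i_s
        gi, gj = active[i_s], active[j_s]
        dij = d[gi, gj]
        li = 0.5 * dij + (r[i_s] - r[j_s]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamp(li, lj)
        lj, li = _clamp(lj, li)
        parent = dendropy.Node()
        parent.add_child(nodes[gi])
        parent.add_child(nodes[gj])
        nodes[gi].edge.length = li
        nodes[gj].edge.length = lj
        new_row = 0.5 * (d[gi, :] + d[gj, :] - dij)
        d = np.vstack([d, new_row])
        d = np.column_stack([d, np.append(new_row, 0.0)])
        nodes.append(parent)
        active = [k for k in active if k not in (gi, gj)] + [len(nodes) - 1]

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    tree = dendropy.Tree(taxon_namespace=tns)
    seed = tree.seed_node
    for k, length in ((a, la), (b, lb), (c, lc)):
        seed.add_child(nodes[k])
        nodes[k].edge.length = max(length, 0.0)
    tree.is_rooted = False
    return tree


def _leafset(node) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def _bipartitions(tree: dendropy.Tree, include_trivial: bool = False):
    """Map each (internal) child edge to the frozenset of leaf labels on
    its far side, canonicalized to the side not containing the anchor
    (first taxon)."""
    all_leaves = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    anchor = min(all_leaves)
    out = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.is_leaf() and not include_trivial:
            continue
        side = _leafset(node)
        if len(side) in (0, len(all_leaves)):
            continue
        key = side if anchor not in side else all_leaves - side
        out[node] = key
    return out, all_leaves


def is_monophyletic(tree: dendropy.Tree, taxa_subset) -> bool:
    """True iff some edge of the unrooted tree splits the leaves into
    exactly (taxa_subset, rest)."""
    subset = frozenset(taxa_subset)
    if not subset:
        raise DataError("empty taxon subset")
    biparts, all_leaves = _bipartitions(tree, include_trivial=True)
    unknown = subset - all_leaves
    if unknown:
        raise DataError(f"unknown taxa: {sorted(unknown)}")
    if subset == all_leaves:
        return True
    anchor = min(all_leaves)
    key = subset if anchor not in subset else all_leaves - subset
    return key in set(biparts.values())


def bootstrap_support(
    alignment: Alignment,
    columns: list[int] | None = None,
    n_reps: int = 500,
    seed: int | None = None,
    model: str = "poisson",
) -> dendropy.Tree:
    """NJ point-estimate tree with bootstrap supports on internal edges.

    Columns (not sequences) are resampled with replacement, the tree is
    rebuilt per replicate, and each internal bipartition of the point
    tree is annotated (node label and ``node.bootstrap_support``) with
    the percentage of replicates containing it.  Replicates whose
    resampled columns make a pair incomparable or saturated are skipped
    with a warning and removed from the denominator.
    """
    if n_reps < 1:
        raise DataError("n_reps must be >= 1")
    if seed is None:
        raise DataError("a seed is required for reproducible bootstraps")
    if columns is None:
        columns = conserved_columns(alignment)
    rng = np.random.default_rng(seed)
    point = neighbor_joining(pairwise_distances(alignment, columns, model))
    biparts, _ = _bipartitions(point)
    counts = {node: 0 for node in biparts}
    effective = 0
    for _ in range(n_reps):
        resampled = list(rng.choice(columns, size=len(columns), replace=True))
        try:
            rep_tree = neighbor_joining(
                pairwise_distances(alignment, resampled, model)
            )
        except DataError as exc:
            warnings.warn(f"bootstrap replicate skipped: {exc}")
            continue
        effective += 1
        rep_keys, _ = _bipartitions(rep_tree)
        rep_set = set(rep_keys.values())
        for node, key in biparts.items():
            if key in rep_set:
                counts[node] += 1
    if effective == 0:
        raise DataError("all bootstrap replicates failed")
    for node, c in counts.items():
        support = 100.0 * c / effective
        node.bootstrap_support = support
        node.label = f"{support:g}"
    return point


def write_newick(tree: dendropy.Tree, path) -> None:
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6g",
    )
    with open(path, "w") as fh:
        fh.write(s)


def read_newick(path) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise DataError(f"malformed Newick in {path}: {exc}") from exc
    tree.is_rooted = False
    for node in tree.preorder_node_iter():
        if node.label is not None and not node.is_leaf():
            try:
                node.bootstrap_support = float(node.label)
            except ValueError:
                pass
    return tree


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Midpoint rooting, for display only."""
    tree = tree.clone(depth=1)
    tree.reroot_at_midpoint(update_bipartitions=False)
    return tree
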
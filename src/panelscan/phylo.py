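"""Nei genetic distances between lines and neighbor-joining trees.

Per-line allele "frequencies" at a locus come from that single line's
genotype: (1, 0) for homozygous allele_a, (0.5, 0.5) for a heterozygote,
(0, 1) for homozygous allele_b; loci missing in either line are skipped.

The default distance is Nei's (1972) standard distance

    D = -ln( Jxy / sqrt(Jx * Jy) )

with Jxy, Jx, Jy the across-loci means of sum_u x_u y_u, sum_u x_u^2 and
sum_u y_u^2.  Nei's DA (1983), 1 - mean_l sum_u sqrt(x_u y_u), is
available as an alternative.  Trees are built with Saitou-Nei neighbor
joining (deterministic tie-break: the smallest (i, j) index pair),
negative branch-length estimates floored at zero with a log note, and
written as standard Newick.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from .errors import ContractError, DataError
from .io import GenotypeMatrix, SnpMap

logger = logging.getLogger(__name__)

__all__ = [
    "TreeNode", "nei_distance_matrix", "nei_distance", "neighbor_joining",
    "tree_to_newick", "write_newick", "tree_distance_matrix",
]


class TreeNode:
    """A node of an (un)rooted phylogenetic tree.

    ``children`` holds (child, branch_length) pairs; a leaf has a name and
    no children.  The root of an unrooted binary tree is a trifurcation.
    """

    __slots__ = ("name", "children")

    def __init__(self, name=None, children=None):
        self.name = name
        self.children = list(children or [])

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list:
        if self.is_leaf():
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


def _line_freq_components(matrix: GenotypeMatrix):
    """Per line x SNP: frequency of allele_a and allele_b, NaN for missing."""
    x = matrix.dosage_float() / 2.0  # allele_b frequency in the line
    return 1.0 - x, x


def nei_distance_matrix(matrix: GenotypeMatrix, variant: str = "nei1972") -> pd.DataFrame:
    """Pairwise Nei distances between all lines.

    ``variant`` is "nei1972" (standard distance) or "da" (Nei 1983 DA).
    Entries are +inf where the lines share no alleles (Jxy = 0) and NaN
    where they share no called loci.
    """
    if variant not in ("nei1972", "da"):
        raise ContractError("variant must be 'nei1972' or 'da'")
    xa, xb = _line_freq_components(matrix)
    called = np.isfinite(xb).astype(float)
    a0 = np.nan_to_num(xa)
    b0 = np.nan_to_num(xb)
    n_shared = called @ called.T
    with np.errstate(invalid="ignore", divide="ignore"):
        if variant == "nei1972":
            jxy = (a0 @ a0.T + b0 @ b0.T) / n_shared
            sq = a0 ** 2 + b0 ** 2
            jx = (sq @ called.T) / n_shared
            jy = jx.T
            ratio = jxy / np.sqrt(jx * jy)
            d = np.where(ratio > 0, -np.log(np.where(ratio > 0, ratio, 1.0)), np.inf)
        else:
            sa, sb = np.sqrt(a0), np.sqrt(b0)
            identity = (sa @ sa.T + sb @ sb.T) / n_shared
            d = 1.0 - identity
        d = np.where(n_shared > 0, d, np.nan)
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)  # guard tiny negative rounding
    return pd.DataFrame(d, index=matrix.line_ids, columns=matrix.line_ids)


def nei_distance(matrix: GenotypeMatrix, smap: SnpMap, line_i: str, line_j: str,
                 variant: str = "nei1972") -> float:
    """Nei distance between two lines of the panel."""
    del smap  # alignment is implied by the matrix
    d = nei_distance_matrix(matrix, variant=variant)
    return float(d.loc[str(line_i), str(line_j)])


def neighbor_joining(distances, labels=None) -> TreeNode:
    """Saitou-Nei neighbor joining on a distance matrix.

    Accepts a square DataFrame (labels from its index) or an ndarray plus
    ``labels``.  Requires n >= 3 finite, symmetric distances with a zero
    diagonal.  Ties in the Q criterion are broken by the smallest (i, j)
    index pair; negative branch-length estimates are floored at zero.
    """
    if isinstance(distances, pd.DataFrame):
        labels = list(distances.index)
        d = distances.to_numpy(dtype=float).copy()
    else:
        d = np.array(distances, dtype=float)
        labels = list(labels) if labels is not None else [str(i) for i in range(len(d))]
    n = d.shape[0]
    if d.shape[0] != d.shape[1] or n != len(labels):
        raise ContractError("distance matrix must be square and match the labels")
    if n < 3:
        raise ContractError("neighbor joining requires at least 3 taxa")
    if not np.all(np.isfinite(d)):
        raise DataError(
            "distance matrix contains non-finite entries; filter loci so all "
            "pairs share polymorphic data before building a tree"
        )
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise ContractError("distance matrix must be symmetric with a zero diagonal")

    nodes = [TreeNode(name=lab) for lab in labels]
    active = list(range(n))

    def floor_len(x: float) -> float:
        if x < 0:
            logger.info("negative NJ branch length %.3g floored at 0", x)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        q[np.tril_indices(m)] = np.inf  # keep i < j; argmin then picks smallest (i, j)
        flat = int(np.argmin(q))
        i, j = divmod(flat, m)
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = floor_len(li), floor_len(lj)
        new = TreeNode(children=[(nodes[active[i]], li), (nodes[active[j]], lj)])
        # distances from the new node to the remaining taxa
        ai, aj = active[i], active[j]
        rest = [a for k, a in enumerate(active) if k not in (i, j)]
        new_d = 0.5 * (d[ai, rest] + d[aj, rest] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, rest] = new_d
        d[rest, -1] = new_d
        nodes.append(new)
        active = rest + [d.shape[0] - 1]

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    return TreeNode(children=[(nodes[a], floor_len(la)), (nodes[b], floor_len(lb)),
                              (nodes[c], floor_len(lc))])


_NEEDS_QUOTE = re.compile(r"[\s()\[\]{}:;,='\"]")


def _format_name(name: str) -> str:
    if name is None:
        return ""
    s = str(name)
    if _NEEDS_QUOTE.search(s):
        return "'" + s.replace("'", "''") + "'"
    return s


def _format_len(x: float) -> str:
    return format(float(x), ".10g")


def tree_to_newick(tree: TreeNode) -> str:
    """Standard Newick string with branch lengths and terminating semicolon."""

    def rec(node: TreeNode) -> str:
        if node.is_leaf():
            return _format_name(node.name)
        inner = ",".join(f"{rec(child)}:{_format_len(bl)}"
                         for child, bl in node.children)
        return f"({inner}){_format_name(node.name) if node.name else ''}"

    return rec(tree) + ";"


def write_newick(tree: TreeNode, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree_to_newick(tree) + "\n")


def tree_distance_matrix(tree: TreeNode) -> pd.DataFrame:
    """Patristic (path-length) distances between all leaf pairs."""
    # each edge is identified by the id() of its child node
    node_paths = {}

    def collect(node, acc):
        if node.is_leaf():
            node_paths[node.name] = acc
        for child, bl in node.children:
            collect(child, acc + [(id(child), bl)])

    collect(tree, [])
    leaves = sorted(node_paths)
    out = pd.DataFrame(0.0, index=leaves, columns=leaves)
    for a in leaves:
        for b in leaves:
            if a >= b:
                continue
            pa, pb = node_paths[a], node_paths[b]
            shared = 0
            for (na, _), (nb, _) in zip(pa, pb):
                if na == nb:
                    shared += 1
                else:
                    break
            dist = sum(bl for _, bl in pa[shared:]) + sum(bl for _, bl in pb[shared:])
            out.loc[a, b] = out.loc[b, a] = dist
    return out
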
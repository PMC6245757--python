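"""Distance-based phylogenetics: K2P distances, neighbor-joining, bootstrap.

The Kimura two-parameter distance corrects pairwise sequence divergence
separately for transitions (A<->G, C<->T; proportion P) and
transversions (proportion Q):

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

Sites where either sequence carries a gap or ambiguity symbol are
excluded pairwise (per pair, not across the whole alignment).  Trees
are built by the canonical neighbor-joining algorithm (Q-criterion join
selection with Studier–Keppler distance updates); internal-edge support
comes from bootstrap resampling of alignment columns, with supports
mapped onto the full-data tree by bipartition identity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("nichebox")

__all__ = [
    "TreeNode",
    "PhyloTree",
    "SaturationError",
    "k2p",
    "k2p_matrix",
    "nj",
    "bootstrap",
    "read_fasta",
    "write_fasta",
    "write_phylip_matrix",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


class SaturationError(ValueError):
    """Pairwise divergence too large for the distance correction."""


# ---------------------------------------------------------------------------
# trees

@dataclass
class TreeNode:
    name: str | None = None
    length: float | None = None          # branch length to the parent
    support: float | None = None         # bootstrap % on the edge above
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.walk() if n.is_leaf()]


@dataclass
class PhyloTree:
    """Unrooted tree stored with an arbitrary internal root (trifurcating)."""

    root: TreeNode

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.leaves()]

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each as the leaf-name side not containing
        the lexicographically first taxon (canonical orientation)."""
        all_leaves = frozenset(self.leaf_names)
        ref = min(all_leaves)
        splits = set()
        for node in self.root.walk():
            if node is self.root or node.is_leaf():
                continue
            side = frozenset(l.name for l in node.leaves())
            if ref in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                splits.add(side)
        return splits

    def to_newick(self, include_support: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                s = node.name or ""
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = ""
                if include_support and node.support is not None:
                    label = f"{node.support:g}"
                s = f"({inner}){label}"
            if node.length is not None:
                s += f":{node.length:.6g}"
            return s

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        import dendropy

        dt = dendropy.Tree.get(data=newick, schema="newick")

        def convert(dnode) -> TreeNode:
            node = TreeNode(
                name=dnode.taxon.label if dnode.taxon else dnode.label,
                length=dnode.edge.length,
            )
            node.children = [convert(c) for c in dnode.child_nodes()]
            return node

        return cls(root=convert(dt.seed_node))


# ---------------------------------------------------------------------------
# K2P distance

def _pair_counts(seq1: str, seq2: str) -> tuple[int, int, int]:
    """(included sites, transitions, transversions) with pairwise deletion."""
    n = ts = tv = 0
    for a, b in zip(seq1.upper(), seq2.upper()):
        if a not in _VALID or b not in _VALID:
            continue
        n += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            ts += 1
        else:
            tv += 1
    return n, ts, tv


def k2p(seq1: str, seq2: str) -> float:
    """Kimura two-parameter distance between two aligned sequences."""
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be equal length")
    n, ts, tv = _pair_counts(seq1, seq2)
    if n == 0:
        raise ValueError("no comparable sites after pairwise deletion")
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"divergence saturated (P={P:.3f}, Q={Q:.3f}); distance undefined"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p_matrix(alignment: dict[str, str]) -> tuple[np.ndarray, list[str]]:
    """Symmetric K2P distance matrix over all sequence pairs."""
    names = list(alignment)
    if len(names) < 2:
        raise ValueError("need at least two sequences")
    lens = {len(s) for s in alignment.values()}
    if len(lens) != 1:
        raise ValueError("sequences must be aligned to equal length")
    n = len(names)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = k2p(alignment[names[i]], alignment[names[j]])
    return D, names


# ---------------------------------------------------------------------------
# neighbor-joining

def nj(D: np.ndarray, labels: list[str]) -> PhyloTree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Join selection minimises ``Q_ij = (n-2) d_ij - r_i - r_j`` (ties
    broken toward the lowest (i, j) in the current label order);
    distances to the new node follow the Studier–Keppler update.
    Negative intermediate branch lengths are clamped to zero with the
    deficit moved to the sister edge.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    if n < 3:
        raise ValueError("neighbor-joining needs at least three taxa")
    if len(labels) != n:
        raise ValueError("label count must match matrix size")

    D = D.copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest (i, j) on ties: flat argmin scans rows then columns
        flat = int(np.argmin(Q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += -li
            li = 0.0
        elif lj < 0:
            li += -lj
            lj = 0.0
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.children = [nodes[i], nodes[j]]
        newd = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [t for t in range(m) if t not in (i, j)]
        D = np.vstack([D[keep][:, keep], newd[keep][None]])
        D = np.hstack([D, np.append(newd[keep], 0.0)[:, None]])
        nodes = [nodes[t] for t in keep] + [parent]

    # final three nodes join at one trifurcating root (three-point formulas)
    a, b, c = nodes
    da = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    db = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    dc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    for node, d in zip((a, b, c), (da, db, dc)):
        node.length = max(d, 0.0)
    return PhyloTree(root=TreeNode(children=[a, b, c]))


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap(alignment: dict[str, str], replicates: int = 1000,
              seed: int = 0) -> PhyloTree:
    """NJ tree with bootstrap supports on internal edges.

    Alignment columns are resampled with replacement ``replicates``
    times; each replicate is rebuilt with K2P + NJ and the support of an
    internal edge of the full-data tree is the percentage of usable
    replicates whose tree contains the same bipartition.  Replicates
    hitting distance saturation are dropped and counted.
    """
    if replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    D, names = k2p_matrix(alignment)
    tree = nj(D, names)
    length = len(next(iter(alignment.values())))
    cols = np.array([list(s) for s in alignment.values()])
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {s: 0 for s in tree.bipartitions()}
    used = 0
    dropped = 0
    for _ in range(replicates):
        idx = rng.integers(0, length, size=length)
        resampled = {
            name: "".join(row) for name, row in zip(alignment, cols[:, idx])
        }
        try:
            Db, nb = k2p_matrix(resampled)
            rep = nj(Db, nb)
        except (SaturationError, ValueError):
            dropped += 1
            continue
        used += 1
        rep_splits = rep.bipartitions()
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    if dropped:
        logger.warning("%d bootstrap replicates dropped (saturation)", dropped)
    if used == 0:
        raise SaturationError("all bootstrap replicates hit saturation")

    all_leaves = frozenset(tree.leaf_names)
    ref = min(all_leaves)
    for node in tree.root.walk():
        if node is tree.root or node.is_leaf():
            continue
        side = frozenset(l.name for l in node.leaves())
        if ref in side:
            side = all_leaves - side
        if side in counts:
            node.support = 100.0 * counts[side] / used
    return tree


# ---------------------------------------------------------------------------
# I/O

def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    aln = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if len({len(s) for s in aln.values()}) > 1:
        raise ValueError("FASTA sequences are not aligned (unequal lengths)")
    return aln


def write_fasta(alignment: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in alignment.items():
            fh.write(f">{name}\n{seq}\n")


def write_phylip_matrix(D: np.ndarray, labels: list[str], path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(labels)}\n")
        for label, row in zip(labels, D):
            fh.write(label.ljust(12) + " ".join(f"{d:.6f}" for d in row) + "\n")
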
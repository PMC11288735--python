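"""Distance-based phylogeny of aligned reverse-transcriptase domains.

p-distances (mismatches / compared columns, pairwise gap deletion) feed a
neighbor-joining agglomeration; bipartition stability is assessed by
bootstrap resampling of alignment columns, and internal branches below a
support cutoff (50% by default) are collapsed into polytomies.  The
agglomeration is implemented here because branch-length clamping is part of
the contract (negative NJ branch lengths are set to zero with the deficit
moved to the sister branch); dendropy is used for Newick interchange.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import CentelineError

GAP_CHARS = frozenset("-?.")


@dataclass
class AlignedBlock:
    """Equal-length gapped rows (nucleotide or amino acid) with unique names."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names/rows length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate taxon names")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("rows differ in length")

    @property
    def n_taxa(self) -> int:
        return len(self.names)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def resample_columns(self, rng: np.random.Generator) -> "AlignedBlock":
        idx = rng.integers(0, self.n_columns, size=self.n_columns)
        rows = ["".join(r[i] for i in idx) for r in self.rows]
        return AlignedBlock(names=list(self.names), rows=rows)


def read_aligned_fasta(path) -> AlignedBlock:
    from .seqio import read_fasta_dict

    d = read_fasta_dict(path)
    return AlignedBlock(names=list(d), rows=list(d.values()))


def pdistance(block: AlignedBlock, gap_handling: str = "pairwise") -> np.ndarray:
    """Pairwise p-distance matrix.

    ``pairwise`` deletion skips, per pair, columns where either row has a
    gap; ``complete`` deletion drops columns gapped in any row before
    comparison.  A pair with zero comparable columns is an error.
    """
    if block.n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    arr = np.array([list(r.upper()) for r in block.rows])
    gap = np.isin(arr, list(GAP_CHARS))
    if gap_handling == "complete":
        keep = ~gap.any(axis=0)
        arr, gap = arr[:, keep], gap[:, keep]
    elif gap_handling != "pairwise":
        raise ValueError(f"unknown gap handling {gap_handling!r}")
    n = block.n_taxa
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            m = int(ok.sum())
            if m == 0:
                raise CentelineError(
                    f"no comparable columns between {block.names[i]} and {block.names[j]}"
                )
            D[i, j] = D[j, i] = float((arr[i, ok] != arr[j, ok]).sum()) / m
    return D


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """A node of an (unrooted, root-trifurcating) tree."""

    name: Optional[str] = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def to_newick(self, with_support: bool = False) -> str:
        return self._newick(with_support) + ";"

    def _newick(self, with_support: bool) -> str:
        if self.is_leaf:
            return self.name
        inner = ",".join(
            f"{child._newick(with_support)}:{blen:.6f}" for child, blen in self.children
        )
        label = ""
        if with_support and self.support is not None:
            label = f"{self.support:.0f}"
        return f"({inner}){label}"


def nj_tree(D: np.ndarray, names: Sequence[str]) -> TreeNode:
    """Neighbor-joining tree from a symmetric non-negative distance matrix.

    Negative branch lengths produced by the NJ formulas are clamped to zero
    and the deficit shifted to the sister branch, preserving the pair's
    total path length.
    """
    D = np.asarray(D, dtype=float)
    n = len(names)
    if D.shape != (n, n):
        raise ValueError("matrix/name shape mismatch")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix is not symmetric")
    if (D < 0).any():
        raise ValueError("negative distances")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=nm) for nm in names]
    D = D.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(Q), Q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        a, b = active[i_], active[j_]
        d_ab = D[a, b]
        li = 0.5 * d_ab + (r[i_] - r[j_]) / (2.0 * (m - 2))
        lj = d_ab - li
        if li < 0:
            lj, li = lj + li, 0.0
        if lj < 0:
            li, lj = li + lj, 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode(children=[(nodes[a], li), (nodes[b], lj)])
        # distances from the new node to the remaining taxa
        new_row = np.zeros(D.shape[0] + 1)
        for k_ in active:
            if k_ in (a, b):
                continue
            new_row[k_] = max(0.0, 0.5 * (D[a, k_] + D[b, k_] - d_ab))
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [x for x in active if x not in (a, b)] + [D.shape[0] - 1]
    # join the last three nodes at an unrooted trifurcation
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = TreeNode(
        children=[
            (nodes[a], max(la, 0.0)),
            (nodes[b], max(lb, 0.0)),
            (nodes[c], max(lc, 0.0)),
        ]
    )
    return root


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each keyed by the side excluding the first taxon."""
    all_leaves = frozenset(tree.leaves())
    ref = min(all_leaves)  # canonicalisation anchor
    out: set[frozenset[str]] = set()

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset()
        for child, _ in node.children:
            side = walk(child)
            if 2 <= len(side) <= len(all_leaves) - 2:
                canon = side if ref not in side else all_leaves - side
                out.add(canon)
            below = below | side
        return below

    walk(tree)
    return out


@dataclass
class SupportTree:
    """A tree annotated with bootstrap support percentages per internal branch."""

    tree: TreeNode
    supports: dict[frozenset[str], float]
    n_reps: int
    cutoff: float

    def to_newick(self) -> str:
        return self.tree.to_newick(with_support=True)


def _annotate_and_collapse(tree: TreeNode, supports, cutoff: float) -> None:
    all_leaves = frozenset(tree.leaves())
    ref = min(all_leaves)

    def walk(node: TreeNode) -> frozenset[str]:
        new_children: list[tuple[TreeNode, float]] = []
        below_all = frozenset()
        for child, blen in node.children:
            side = walk(child)
            below_all |= side
            if not child.is_leaf and 2 <= len(side) <= len(all_leaves) - 2:
                canon = side if ref not in side else all_leaves - side
                sup = supports.get(canon, 0.0)
                child.support = sup
                if sup < cutoff:
                    # collapse: promote grandchildren, absorbing the branch
                    for gc, gblen in child.children:
                        new_children.append((gc, gblen))
                    continue
            new_children.append((child, blen))
        node.children = new_children
        if node.is_leaf:
            return frozenset([node.name])
        return below_all

    walk(tree)


def bootstrap_support(
    block: AlignedBlock,
    n_reps: int = 1000,
    seed: int = 0,
    cutoff: float = 50.0,
    gap_handling: str = "pairwise",
) -> SupportTree:
    """NJ tree with bootstrap supports; branches under ``cutoff``% collapse.

    Columns are resampled with replacement ``n_reps`` times; the support of
    each internal branch of the original tree is the percentage of replicate
    trees containing the same bipartition.
    """
    if n_reps < 1:
        raise ValueError("need at least 1 bootstrap replicate")
    base = nj_tree(pdistance(block, gap_handling), block.names)
    base_bips = bipartitions(base)
    counts = {bip: 0 for bip in base_bips}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        rep = block.resample_columns(rng)
        try:
            rep_tree = nj_tree(pdistance(rep, gap_handling), rep.names)
        except CentelineError:
            continue  # replicate dropped a pair's comparable columns entirely
        rep_bips = bipartitions(rep_tree)
        for bip in base_bips:
            if bip in rep_bips:
                counts[bip] += 1
    supports = {bip: 100.0 * c / n_reps for bip, c in counts.items()}
    _annotate_and_collapse(base, supports, cutoff)
    return SupportTree(tree=base, supports=supports, n_reps=n_reps, cutoff=cutoff)
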
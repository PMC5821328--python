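"""Neighbor-joining phylogeny of aligned amino-acid regions with bootstrap.

Distances: p-distance (mismatches / compared sites) or Poisson
correction ``d = -ln(1 - p)``, with pairwise deletion of gap columns.
Tree inference is the standard Saitou-Nei Q-criterion agglomeration with
negative branch lengths clamped to zero (original values logged) and
ties broken by the lexicographically smallest leaf-label pair. Bootstrap
resamples included columns with replacement (seeded; replicate column
indices retained for audit) and scores each internal bipartition of the
original tree by the percentage of replicate trees containing it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .seqtools import read_fasta

GAP_CHARS = frozenset("-.")


@dataclass
class MsAlignment:
    """Equal-length aligned amino-acid rows with an included-position mask."""

    names: list[str]
    rows: list[str]
    mask: list[bool] | None = None

    def __post_init__(self):
        if len(self.names) != len(self.rows):
            raise ValueError("names/rows length mismatch")
        if len(self.names) < 3:
            raise ValueError("alignment needs at least 3 taxa")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths {sorted(lengths)}")
        if self.mask is not None and len(self.mask) != len(self.rows[0]):
            raise ValueError("mask length != alignment length")

    @property
    def included_columns(self) -> np.ndarray:
        n = len(self.rows[0])
        if self.mask is None:
            return np.arange(n)
        return np.nonzero(np.asarray(self.mask, dtype=bool))[0]

    def column_matrix(self, columns: np.ndarray | None = None) -> np.ndarray:
        """(taxa x columns) byte matrix restricted to the given columns."""
        mat = np.array([np.frombuffer(r.encode("ascii"), dtype=np.uint8) for r in self.rows])
        cols = self.included_columns if columns is None else columns
        return mat[:, cols]

    @classmethod
    def from_fasta(cls, path) -> "MsAlignment":
        records = read_fasta(path)
        return cls([r[0] for r in records], [r[2].upper() for r in records])

    @classmethod
    def from_phylip(cls, path) -> "MsAlignment":
        """Relaxed sequential PHYLIP: 'ntaxa ncols' header, 'name sequence' rows."""
        with open(path) as fh:
            header = fh.readline().split()
            n_taxa = int(header[0])
            names, rows = [], []
            for line in fh:
                if not line.strip():
                    continue
                name, seq = line.split(None, 1)
                names.append(name)
                rows.append(seq.replace(" ", "").strip().upper())
        if len(names) != n_taxa:
            raise ValueError(f"expected {n_taxa} taxa, parsed {len(names)}")
        return cls(names, rows)


_GAP_CODES = frozenset(ord(c) for c in GAP_CHARS)


def pairwise_distances(
    aln: MsAlignment, model: str = "poisson", columns: np.ndarray | None = None
) -> np.ndarray:
    """Symmetric distance matrix under p-distance or Poisson correction.

    Gap columns are deleted pairwise: only sites where both rows carry a
    residue are compared. A pair with no comparable sites, or with p = 1
    under the Poisson model, raises ValueError.
    """
    if model not in ("p-distance", "p", "poisson"):
        raise ValueError(f"unknown model {model!r}")
    mat = aln.column_matrix(columns)
    n = mat.shape[0]
    not_gap = np.ones(mat.shape, dtype=bool)
    for code in _GAP_CODES:
        not_gap &= mat != code
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = not_gap[i] & not_gap[j]
            compared = int(both.sum())
            if compared == 0:
                raise ValueError(
                    f"no comparable sites between {aln.names[i]} and {aln.names[j]}"
                )
            p = float((mat[i][both] != mat[j][both]).sum()) / compared
            if model in ("p", "p-distance"):
                d = p
            else:
                if p >= 1.0:
                    raise ValueError(
                        f"saturated pair {aln.names[i]}/{aln.names[j]} (p = 1)"
                    )
                d = -math.log(1.0 - p)
            dist[i, j] = dist[j, i] = d
    return dist


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self, length: float | None = None) -> str:
        if not self.children:
            body = self.name
        else:
            inner = ",".join(c._newick_inner(bl) for c, bl in self.children)
            label = "" if self.support is None else f"{self.support:g}"
            body = f"({inner}){label}"
        if length is None:
            return body
        return f"{body}:{length:.6g}"


@dataclass
class PhyloTree:
    """Unrooted tree (rooted representation at the final join) + clamp log."""

    root: TreeNode
    clamped: list[tuple[str, float]] = field(default_factory=list)
    n_bootstrap: int = 0
    replicate_columns: list[np.ndarray] | None = None

    def newick(self) -> str:
        return self.root.newick()

    def leaf_names(self) -> list[str]:
        return sorted(self.root.leaves())

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, canonicalized as the side without the
        lexicographically smallest taxon."""
        all_leaves = set(self.root.leaves())
        ref = min(all_leaves)
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode):
            for child, _ in node.children:
                side = set(child.leaves())
                if 1 < len(side) < len(all_leaves) - 1:
                    canon = side if ref not in side else all_leaves - side
                    out.add(frozenset(canon))
                walk(child)

        walk(self.root)
        return out

    def internal_nodes(self) -> list[TreeNode]:
        out = []

        def walk(node: TreeNode, is_root: bool):
            if node.children and not is_root:
                out.append(node)
            for child, _ in node.children:
                walk(child, False)

        walk(self.root, True)
        return out


def neighbor_joining(dist: np.ndarray, names: list[str]) -> PhyloTree:
    """Saitou-Nei neighbor joining of a symmetric distance matrix.

    Ties in the Q criterion are broken by the lexicographically smallest
    (min leaf label, max leaf label) pair, making the result independent
    of input taxon order. Negative branch lengths are clamped to zero
    and logged in ``PhyloTree.clamped``.
    """
    dist = np.asarray(dist, dtype=float)
    n = len(names)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix is not symmetric")

    clamped: list[tuple[str, float]] = []

    def clamp(label: str, value: float) -> float:
        if value < 0:
            clamped.append((label, value))
            return 0.0
        return value

    nodes: list[TreeNode] = [TreeNode(name=nm) for nm in names]
    keys: list[str] = list(names)  # min leaf label under each active node
    D = dist.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        li = clamp(keys[i], li)
        lj = clamp(keys[j], lj)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # grow the matrix with the new node's distances
        D = np.pad(D, ((0, 1), (0, 1)))
        u = D.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            D[u, k] = D[k, u] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes.append(new)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    la = clamp(keys[a], 0.5 * (D[a, b] + D[a, c] - D[b, c]))
    lb = clamp(keys[b], 0.5 * (D[a, b] + D[b, c] - D[a, c]))
    lc = clamp(keys[c], 0.5 * (D[a, c] + D[b, c] - D[a, b]))
    root = TreeNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return PhyloTree(root=root, clamped=clamped)


def nj_tree(aln: MsAlignment, model: str = "poisson") -> PhyloTree:
    return neighbor_joining(pairwise_distances(aln, model), aln.names)


def bootstrap(
    aln: MsAlignment, n_reps: int = 500, seed: int = 0, model: str = "poisson"
) -> PhyloTree:
    """NJ tree with bootstrap support percentages on internal branches.

    Included columns are resampled with replacement per replicate; each
    internal bipartition of the original tree is scored by the
    percentage of replicate trees containing it. ``n_reps = 0`` returns
    the tree without support values.
    """
    tree = nj_tree(aln, model)
    if n_reps == 0:
        return tree
    rng = np.random.default_rng(seed)
    cols = aln.included_columns
    counts: dict[frozenset, int] = {bp: 0 for bp in tree.bipartitions()}
    replicate_cols: list[np.ndarray] = []
    for _ in range(n_reps):
        sampled = rng.choice(cols, size=len(cols), replace=True)
        replicate_cols.append(sampled)
        rep_dist = pairwise_distances(aln, model, columns=sampled)
        rep_tree = neighbor_joining(rep_dist, aln.names)
        rep_bps = rep_tree.bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1

    all_leaves = set(tree.root.leaves())
    ref = min(all_leaves)
    for node in tree.internal_nodes():
        side = set(node.leaves())
        canon = frozenset(side if ref not in side else all_leaves - side)
        if canon in counts:
            node.support = 100.0 * counts[canon] / n_reps
    tree.n_bootstrap = n_reps
    tree.replicate_columns = replicate_cols
    return tree


def write_distance_tsv(dist: np.ndarray, names: list[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\t" + "\t".join(names) + "\n")
        for i, nm in enumerate(names):
            fh.write(nm + "\t" + "\t".join(f"{dist[i, j]:.6g}" for j in range(len(names))) + "\n")
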
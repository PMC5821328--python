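"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package's search/assembly
paths: plain-Python dynamic programming and exhaustive enumeration only.
"""

from __future__ import annotations

import numpy as np

NEG_INF = float("-inf")

# BLOSUM62 values are read from Biopython's matrix object but the
# alignment itself is an independent pure-Python Gotoh implementation.
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def blosum62(a: str, b: str) -> float:
    return float(_B62[a][b])


def smith_waterman(query: str, subject: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Max local alignment score, affine gaps (length-g gap costs open + g*extend)."""
    n, m = len(query), len(subject)
    best = 0.0
    H_prev = [0.0] * (m + 1)
    E_prev = [NEG_INF] * (m + 1)
    first_gap = gap_open + gap_extend
    for i in range(1, n + 1):
        H_row = [0.0] * (m + 1)
        E_row = [NEG_INF] * (m + 1)
        F = NEG_INF
        qi = query[i - 1]
        for j in range(1, m + 1):
            E = max(H_prev[j] - first_gap, E_prev[j] - gap_extend)
            F = max(H_row[j - 1] - first_gap, F - gap_extend)
            diag = H_prev[j - 1] + blosum62(qi, subject[j - 1])
            h = max(0.0, diag, E, F)
            H_row[j] = h
            E_row[j] = E
            if h > best:
                best = h
        H_prev, E_prev = H_row, E_row
    return best


_CODONS = {}


def _codon_table():
    if not _CODONS:
        from virowinnow.seqtools import CODON_TABLE

        _CODONS.update(CODON_TABLE)
    return _CODONS


def _translate(seq: str) -> str:
    table = _codon_table()
    return "".join(
        table.get(seq[i : i + 3], "X") for i in range(0, len(seq) - len(seq) % 3, 3)
    )


_COMP = str.maketrans("ACGTN", "TGCAN")


def exhaustive_translated_best(seq: str, db: list) -> tuple[float, set[str]]:
    """Best raw Smith-Waterman score over all 6 frames x all subjects.

    Returns (best score, ids of subjects attaining it). ``db`` is a list
    of objects with ``id`` and ``sequence``.
    """
    rc = seq.translate(_COMP)[::-1]
    frames = [
        _translate(seq), _translate(seq[1:]), _translate(seq[2:]),
        _translate(rc), _translate(rc[1:]), _translate(rc[2:]),
    ]
    best = 0.0
    winners: set[str] = set()
    for rec in db:
        for frame in frames:
            score = smith_waterman(frame, rec.sequence)
            if score > best:
                best = score
                winners = {rec.id}
            elif score == best:
                winners.add(rec.id)
    return best, winners


def all_pairs_overlaps(reads, l_min: int, i_min: float) -> dict:
    """Exhaustive best overlap per pair: every orientation and every shift.

    Returns {(i_id, j_id): (score, length, orientation, shift)} using the
    same preference order as the implementation (score, length, '+'
    before '-', smaller shift) but derived by plain enumeration.
    """
    def rc(s):
        return s.translate(_COMP)[::-1]

    out = {}
    reads = list(reads)
    for a in range(len(reads)):
        for b in range(a + 1, len(reads)):
            si = reads[a].sequence
            best = None
            for orient, sj in (("+", reads[b].sequence), ("-", rc(reads[b].sequence))):
                for shift in range(-(len(sj) - l_min), len(si) - l_min + 1):
                    start = max(0, shift)
                    end = min(len(si), shift + len(sj))
                    ovl = end - start
                    if ovl < l_min:
                        continue
                    matches = sum(
                        1
                        for x, y in zip(si[start:end], sj[start - shift : end - shift])
                        if x == y and x != "N"
                    )
                    if 100.0 * matches / ovl < i_min:
                        continue
                    cand = (matches, ovl, orient, shift)
                    if best is None or _pref(cand) > _pref(best):
                        best = cand
            if best is not None:
                out[(reads[a].id, reads[b].id)] = best
    return out


def _pref(cand):
    matches, ovl, orient, shift = cand
    return (matches, ovl, orient == "+", -shift)


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random binary unrooted tree; returns (distance matrix, names, bipartitions).

    Built by sequential random joins with branch lengths in [0.1, 1.0];
    leaf-to-leaf path lengths give an exactly additive matrix.
    """
    names = [f"T{i}" for i in range(n_taxa)]
    # adjacency of a tree built by random leaf attachment
    edges: dict[int, list[tuple[int, float]]] = {0: [], 1: [], 2: []}
    next_id = n_taxa
    center = next_id
    next_id += 1
    edges[center] = []

    def link(u, v, w):
        edges.setdefault(u, []).append((v, w))
        edges.setdefault(v, []).append((u, w))

    for leaf in (0, 1, 2):
        link(leaf, center, float(rng.uniform(0.1, 1.0)))
    existing_edges = [(0, center), (1, center), (2, center)]
    for leaf in range(3, n_taxa):
        u, v = existing_edges[rng.integers(len(existing_edges))]
        w_uv = next(w for x, w in edges[u] if x == v)
        mid = next_id
        next_id += 1
        split = float(rng.uniform(0.25, 0.75)) * w_uv
        edges[u] = [(x, w) for x, w in edges[u] if x != v]
        edges[v] = [(x, w) for x, w in edges[v] if x != u]
        edges[mid] = []
        link(u, mid, split)
        link(mid, v, w_uv - split)
        link(leaf, mid, float(rng.uniform(0.1, 1.0)))
        existing_edges.remove((u, v))
        existing_edges.extend([(u, mid), (mid, v), (leaf, mid)])

    # all-pairs path lengths between leaves
    import heapq

    dist = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        d = {src: 0.0}
        heap = [(0.0, src)]
        while heap:
            dd, u = heapq.heappop(heap)
            if dd > d.get(u, float("inf")):
                continue
            for v, w in edges[u]:
                nd = dd + w
                if nd < d.get(v, float("inf")):
                    d[v] = nd
                    heapq.heappush(heap, (nd, v))
        for dst in range(n_taxa):
            dist[src, dst] = d[dst]

    # true non-trivial bipartitions: removing each internal edge
    leaves = set(range(n_taxa))
    ref = "T0"
    bps = set()
    for u in edges:
        for v, _ in edges[u]:
            if u >= v:
                continue
            # collect leaves on v's side with edge u-v removed
            side = set()
            stack = [v]
            seen = {u, v}
            while stack:
                x = stack.pop()
                if x < n_taxa:
                    side.add(x)
                for y, _ in edges[x]:
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
            if 1 < len(side) < n_taxa - 1:
                names_side = {f"T{i}" for i in side}
                if ref in names_side:
                    names_side = {f"T{i}" for i in leaves - side}
                bps.add(frozenset(names_side))
    return dist, names, bps
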
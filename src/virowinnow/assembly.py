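"""Greedy overlap-layout-consensus assembly of virus-binned reads.

Overlaps are suffix-prefix (either orientation) ungapped overlaps of
length >= ``l_min`` and identity >= ``i_min``; the overlap score is
``length x identity`` which, with identity as a fraction, equals the
match count. Contigs are built by repeatedly merging the
highest-scoring overlap between distinct layouts; the consensus is a
per-column majority vote with ties broken by fixed base order
A < C < G < T. Per-library singleton membership is tallied from read
labels.

Candidate overlap generation is exact all-pairs/all-shifts for small
inputs and k-mer seeded (shared 16-mers propose shifts) for large ones;
both paths verify candidates identically.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .seqtools import encode_dna, revcomp

L_MIN = 40
I_MIN = 90.0
SEED_K = 16
EXHAUSTIVE_MAX_READS = 60


@dataclass(frozen=True)
class Overlap:
    """Best overlap for an unordered read pair.

    ``shift`` places read j (forward if orientation '+', reverse
    complement if '-') relative to the forward start of read i.
    ``score`` is the match count (= length x fractional identity).
    """

    i_id: str
    j_id: str
    orientation: str  # '+' or '-'
    shift: int
    length: int
    identity: float  # percent
    score: int


@dataclass
class Contig:
    id: str
    consensus: str
    members: list[str]
    library_counts: dict[str, int]

    @property
    def total(self) -> int:
        return len(self.members)


def _candidate_pairs_exhaustive(n: int, lengths: list[int], l_min: int):
    for i in range(n):
        for j in range(i + 1, n):
            for orient in ("+", "-"):
                for shift in range(-(lengths[j] - l_min), lengths[i] - l_min + 1):
                    yield i, j, orient, shift


#: per-kmer bucket size up to which every pair is proposed; above it only
#: nearby entries are linked (high-coverage data has abundant redundancy)
PAIR_BUCKET_CAP = 64


def _candidate_pairs_seeded(
    fwd: list[np.ndarray], rev: list[np.ndarray], k: int
) -> set[tuple[int, int, str, int]]:
    """Shift candidates from shared k-mers.

    Within each k-mer bucket all pairs are proposed up to
    ``PAIR_BUCKET_CAP`` entries; larger buckets fall back to linking
    nearby entries, which preserves assembly connectivity at deep
    coverage without a quadratic blowup.
    """
    pow4 = (4 ** np.arange(k, dtype=np.int64))[::-1]
    hashes, rids, poss, strands = [], [], [], []
    for strand_code, mats in ((0, fwd), (1, rev)):
        for rid, arr in enumerate(mats):
            if len(arr) < k:
                continue
            win = np.lib.stride_tricks.sliding_window_view(arr, k)
            ok = ~(win == 4).any(axis=1)
            h = win.astype(np.int64) @ pow4
            idx = np.nonzero(ok)[0]
            hashes.append(h[idx])
            rids.append(np.full(len(idx), rid, dtype=np.int64))
            poss.append(idx.astype(np.int64))
            strands.append(np.full(len(idx), strand_code, dtype=np.int64))
    if not hashes:
        return set()
    h = np.concatenate(hashes)
    rid = np.concatenate(rids)
    pos = np.concatenate(poss)
    strand = np.concatenate(strands)
    order = np.argsort(h, kind="stable")
    h, rid, pos, strand = h[order], rid[order], pos[order], strand[order]

    lengths = np.array([len(a) for a in fwd], dtype=np.int64)
    cands: set[tuple[int, int, str, int]] = set()
    run_starts = np.concatenate(([0], np.nonzero(np.diff(h))[0] + 1, [len(h)]))
    for s, e in zip(run_starts[:-1], run_starts[1:]):
        size = e - s
        if size < 2:
            continue
        if size <= PAIR_BUCKET_CAP:
            pairs = (
                (ia, ib) for ia in range(s, e) for ib in range(ia + 1, e)
            )
        else:
            pairs = (
                (ia, ia + d) for d in (1, 2) for ia in range(s, e - d)
            )
        for ia, ib in pairs:
            r1, r2 = int(rid[ia]), int(rid[ib])
            if r1 == r2:
                continue
            s1, s2 = int(strand[ia]), int(strand[ib])
            p1, p2 = int(pos[ia]), int(pos[ib])
            cands.add(_normalize(r1, s1, p1, r2, s2, p2, lengths))
    return cands


def _normalize(r1, s1, p1, r2, s2, p2, lengths) -> tuple[int, int, str, int]:
    """Canonical (i<j, orientation, shift) for one shared-kmer candidate."""
    # express as: r1 forward, r2 oriented, at some shift
    if s1 == 0:
        orient = "+" if s2 == 0 else "-"
        shift = p1 - p2
    else:
        # r1 entry is on the reverse strand: mirror the whole arrangement
        orient = "-" if s2 == 0 else "+"
        shift = lengths[r1] - (p1 - p2) - lengths[r2]
    if r1 <= r2:
        return (r1, r2, orient, shift)
    # swap reference read: i forward with j oriented at shift ->
    # j forward with i oriented at shift'
    if orient == "+":
        return (r2, r1, "+", -shift)
    return (r2, r1, "-", shift + lengths[r2] - lengths[r1])


def _verify(
    cands, fwd, rev, lengths, l_min: int, i_min: float
) -> dict[tuple[int, int], tuple]:
    """Verify candidates; keep the best qualifying overlap per pair.

    Returns pair -> (score, length, identity, orient, shift).
    """
    best: dict[tuple[int, int], tuple] = {}
    for i, j, orient, shift in cands:
        li, lj = lengths[i], lengths[j]
        start = max(0, shift)
        end = min(li, shift + lj)
        ovl = end - start
        if ovl < l_min:
            continue
        a = fwd[i][start:end]
        b = (fwd[j] if orient == "+" else rev[j])[start - shift : end - shift]
        matches = int(((a == b) & (a != 4)).sum())
        identity = 100.0 * matches / ovl
        if identity < i_min:
            continue
        # deterministic preference: score, length, '+' before '-', smaller shift
        cand = (matches, ovl, identity, orient, shift)
        key = (i, j)
        prev = best.get(key)
        if prev is None or (cand[0], cand[1], prev[3], -cand[4]) > (
            prev[0], prev[1], cand[3], -prev[4]
        ):
            best[key] = cand
    return best


def find_overlaps(
    reads,
    l_min: int = L_MIN,
    i_min: float = I_MIN,
    seed_k: int = SEED_K,
    mode: str = "auto",
) -> list[Overlap]:
    """Best qualifying overlap per read pair (either orientation).

    ``mode`` is "exhaustive" (all pairs, all shifts), "seeded" (shared
    k-mers propose shifts), or "auto" (exhaustive up to
    ``EXHAUSTIVE_MAX_READS`` reads).
    """
    reads = list(reads)
    n = len(reads)
    fwd = [encode_dna(r.sequence) for r in reads]
    rev = [encode_dna(revcomp(r.sequence)) for r in reads]
    lengths = [len(a) for a in fwd]

    if mode == "auto":
        mode = "exhaustive" if n <= EXHAUSTIVE_MAX_READS else "seeded"
    if mode == "exhaustive":
        cands = _candidate_pairs_exhaustive(n, lengths, l_min)
    elif mode == "seeded":
        cands = _candidate_pairs_seeded(fwd, rev, seed_k)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    best = _verify(cands, fwd, rev, lengths, l_min, i_min)
    overlaps = []
    for (i, j), (matches, ovl, identity, orient, shift) in best.items():
        overlaps.append(
            Overlap(reads[i].id, reads[j].id, orient, shift, ovl, identity, matches)
        )
    overlaps.sort(key=lambda o: (-o.score, -o.length, o.i_id, o.j_id))
    return overlaps


class _Layouts:
    """Read placements grouped into components (orientation + offset)."""

    def __init__(self, reads):
        self.lengths = {r.id: len(r.sequence) for r in reads}
        self.comp_of = {r.id: r.id for r in reads}
        # comp id -> {read id: (orient, offset)}
        self.members = {r.id: {r.id: (1, 0)} for r in reads}

    def merge(self, ovl: Overlap) -> bool:
        ca, cb = self.comp_of[ovl.i_id], self.comp_of[ovl.j_id]
        if ca == cb:
            return False
        o_i, t_i = self.members[ca][ovl.i_id]
        li, lj = self.lengths[ovl.i_id], self.lengths[ovl.j_id]
        sign = 1 if ovl.orientation == "+" else -1
        if o_i == 1:
            o_ja, t_ja = sign, t_i + ovl.shift
        else:
            o_ja, t_ja = -sign, t_i + li - ovl.shift - lj
        o_jb, t_jb = self.members[cb][ovl.j_id]

        if len(self.members[cb]) > len(self.members[ca]):
            # merge the smaller component; re-derive the transform with roles swapped
            return self.merge(
                Overlap(ovl.j_id, ovl.i_id, ovl.orientation,
                        -ovl.shift if ovl.orientation == "+" else ovl.shift + lj - li,
                        ovl.length, ovl.identity, ovl.score)
            )

        if o_ja == o_jb:
            delta = t_ja - t_jb
            for rid, (o, t) in self.members[cb].items():
                self.members[ca][rid] = (o, t + delta)
                self.comp_of[rid] = ca
        else:
            for rid, (o, t) in self.members[cb].items():
                self.members[ca][rid] = (-o, t_ja + t_jb + lj - t - self.lengths[rid])
                self.comp_of[rid] = ca
        del self.members[cb]
        return True


def greedy_assemble(reads, overlaps) -> tuple[list[Contig], list]:
    """Merge overlaps best-first; returns (contigs, leftover singleton reads)."""
    reads = list(reads)
    by_id = {r.id: r for r in reads}
    layouts = _Layouts(reads)
    for ovl in sorted(overlaps, key=lambda o: (-o.score, -o.length, o.i_id, o.j_id)):
        layouts.merge(ovl)

    fwd = {r.id: encode_dna(r.sequence) for r in reads}
    rev = {r.id: encode_dna(revcomp(r.sequence)) for r in reads}

    components = [m for m in layouts.members.values() if len(m) >= 2]
    components.sort(key=lambda m: (-len(m), min(m)))
    contigs: list[Contig] = []
    for idx, members in enumerate(components, 1):
        t0 = min(t for _, t in members.values())
        span = max(t + layouts.lengths[rid] for rid, (_, t) in members.items()) - t0
        counts = np.zeros((span, 4), dtype=np.int32)
        for rid, (o, t) in members.items():
            arr = fwd[rid] if o == 1 else rev[rid]
            posmask = arr != 4
            positions = np.arange(len(arr))[posmask] + (t - t0)
            np.add.at(counts, (positions, arr[posmask]), 1)
        consensus_codes = counts.argmax(axis=1)
        consensus = np.array(list("ACGT"))[consensus_codes]
        consensus[counts.sum(axis=1) == 0] = "N"
        member_ids = sorted(members)
        contigs.append(
            Contig(
                id=f"contig_{idx}",
                consensus="".join(consensus),
                members=member_ids,
                library_counts=dict(Counter(by_id[rid].library for rid in member_ids)),
            )
        )
    leftovers = [
        by_id[rid]
        for m in layouts.members.values()
        if len(m) == 1
        for rid in m
    ]
    leftovers.sort(key=lambda r: r.id)
    return contigs, leftovers


def write_contigs_fasta(contigs: list[Contig], path) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id} members={c.total}\n{c.consensus}\n")


def write_membership_tsv(contigs: list[Contig], by_id, path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tread_id\tlibrary\n")
        for c in contigs:
            for rid in c.members:
                fh.write(f"{c.id}\t{rid}\t{by_id[rid].library}\n")
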
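"""Six-frame translated homology search with taxonomic binning.

The search is BLASTX-like: exact amino-acid word seeds (default word
size 3) in all six reading frames select candidate subjects, which are
then aligned by local dynamic programming (Smith-Waterman with affine
gaps, BLOSUM62, gap open 11 / extend 1, i.e. a gap of length g costs
11 + g). The best hit is scored with the gapped Karlin-Altschul
constants lambda = 0.267, K = 0.041:

    bit score S' = (lambda * S - ln K) / ln 2
    E = m * n * 2**(-S')

with m the query length in amino acids (nt length // 3) and n the total
residue count of the database (no length correction).

Candidate pruning: subjects sharing many seed words are aligned first
and weakly seeded subjects are skipped when a strong candidate exists
(``prune=True``, the default); with ``prune=False`` every subject
sharing at least one word is aligned, which reproduces exhaustive
Smith-Waterman whenever the optimal alignment contains an exact word
match.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .seqtools import revcomp, translate

TAXON_BINS = frozenset(
    {"Animal", "Plant", "Fungi", "Bacteria", "Archaea", "Protist", "Phage", "NonPhageVirus"}
)

WORD_SIZE = 3
GAP_OPEN = 11
GAP_EXTEND = 1
LAMBDA = 0.267
KAPPA = 0.041
E_VALUE_THRESHOLD = 1e-5
PHIX_MARKER = "phix"

FRAME_ORDER = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class ProteinRecord:
    """A taxonomically labeled protein database record."""

    id: str
    sequence: str
    taxon_bin: str
    species: str
    genome_type: str | None = None  # virus records: ssRNA / RNA / ssDNA / dsDNA
    plant_host: bool = False  # plant-infecting virus

    def __post_init__(self):
        if self.taxon_bin not in TAXON_BINS:
            raise ValueError(f"unknown taxon bin {self.taxon_bin!r} for {self.id}")

    @property
    def is_phix(self) -> bool:
        return PHIX_MARKER in self.species.lower()


@dataclass(frozen=True)
class HomologyHit:
    """Best translated-alignment match of a query to a database record."""

    query_id: str
    subject_id: str
    frame: int  # in {+-1, +-2, +-3}
    raw_score: float
    bit_score: float
    e_value: float
    percent_identity: float  # over aligned columns, [0, 100]
    query_coverage: float  # % of the query frame spanned, [0, 100]
    taxon_bin: str


def six_frame_translate(seq: str) -> dict[int, str]:
    """Translations of frames +1..+3 and -1..-3 (reverse complement).

    Stop codons are rendered as ``*``; trailing partial codons dropped.
    """
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    rc = revcomp(seq)
    return {
        1: translate(seq),
        2: translate(seq[1:]),
        3: translate(seq[2:]),
        -1: translate(rc),
        -2: translate(rc[1:]),
        -3: translate(rc[2:]),
    }


def karlin_altschul(raw_score: float, m: int, n: int,
                    lam: float = LAMBDA, kappa: float = KAPPA) -> tuple[float, float]:
    """(bit score, E-value) for a raw alignment score in an m x n search space."""
    bit = (lam * raw_score - math.log(kappa)) / math.log(2)
    e_value = m * n * 2.0 ** (-bit)
    return bit, e_value


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # a gap of length g costs GAP_OPEN + g * GAP_EXTEND
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


def alignment_stats(alignment) -> tuple[float, int, int]:
    """(percent identity over aligned columns, query span start, query span end).

    Expects alignments produced as ``aligner.align(query_frame, subject)``;
    Biopython calls the first sequence "target", so the read frame is
    ``alignment.target`` and its blocks are ``alignment.aligned[0]``.
    """
    q_blocks, s_blocks = alignment.aligned
    query, subject = alignment.target, alignment.query
    matches = 0
    block_cols = 0
    for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
        block_cols += qe - qs
        for a, b in zip(query[qs:qe], subject[ss:se]):
            if a == b:
                matches += 1
    gap_cols = 0
    for i in range(1, len(q_blocks)):
        gap_cols += q_blocks[i][0] - q_blocks[i - 1][1]
        gap_cols += s_blocks[i][0] - s_blocks[i - 1][1]
    total_cols = block_cols + gap_cols
    identity = 100.0 * matches / total_cols if total_cols else 0.0
    return identity, int(q_blocks[0][0]), int(q_blocks[-1][1])


class HomologySearcher:
    """Seeded six-frame translated search against a labeled protein database."""

    def __init__(
        self,
        db: list[ProteinRecord],
        word_size: int = WORD_SIZE,
        lam: float = LAMBDA,
        kappa: float = KAPPA,
        prune: bool = True,
    ):
        if not db:
            raise ValueError("protein database is empty")
        self.db = list(db)
        self.by_id = {rec.id: rec for rec in self.db}
        self.word_size = word_size
        self.lam = lam
        self.kappa = kappa
        self.prune = prune
        self.total_residues = sum(len(rec.sequence) for rec in self.db)
        self._aligner = _make_aligner()
        self._index: dict[str, set[int]] = {}
        for idx, rec in enumerate(self.db):
            seq = rec.sequence
            for i in range(len(seq) - word_size + 1):
                self._index.setdefault(seq[i : i + word_size], set()).add(idx)

    def _seed_counts(self, frame_seq: str) -> dict[int, int]:
        counts: dict[int, int] = {}
        w = self.word_size
        for i in range(len(frame_seq) - w + 1):
            word = frame_seq[i : i + w]
            if "*" in word or "X" in word:
                continue
            for idx in self._index.get(word, ()):
                counts[idx] = counts.get(idx, 0) + 1
        return counts

    def search(self, query_id: str, seq: str) -> HomologyHit | None:
        """Best hit over all six frames, or None when no word seeds."""
        seq = seq.upper()
        if set(seq) - set("ACGTN"):
            raise ValueError(
                f"query {query_id}: non-ACGTN characters {sorted(set(seq) - set('ACGTN'))}"
            )
        frames = six_frame_translate(seq)

        seeded: list[tuple[int, int, int]] = []  # (frame, subject_idx, word_count)
        best_count = 0
        for frame in FRAME_ORDER:
            for idx, count in self._seed_counts(frames[frame]).items():
                seeded.append((frame, idx, count))
                best_count = max(best_count, count)
        if not seeded:
            return None

        if self.prune and best_count >= 4:
            cutoff = max(2, best_count // 2)
            seeded = [t for t in seeded if t[2] >= cutoff]

        best: tuple[float, int, int] | None = None  # (score, frame, idx)
        tied: list[tuple[int, int]] = []
        for frame, idx, _count in seeded:
            score = self._aligner.score(frames[frame], self.db[idx].sequence)
            if best is None or score > best[0]:
                best = (score, frame, idx)
                tied = [(frame, idx)]
            elif score == best[0]:
                tied.append((frame, idx))

        raw = best[0]
        choice = None
        frame_rank = {f: i for i, f in enumerate(FRAME_ORDER)}
        for frame, idx in tied:
            aln = self._aligner.align(frames[frame], self.db[idx].sequence)[0]
            identity, q_start, q_end = alignment_stats(aln)
            coverage = 100.0 * (q_end - q_start) / len(frames[frame])
            key = (-identity, self.db[idx].id, frame_rank[frame])
            if choice is None or key < choice[0]:
                choice = (key, frame, idx, identity, coverage)

        _, frame, idx, identity, coverage = choice
        m = max(len(seq) // 3, 1)
        bit, e_value = karlin_altschul(raw, m, self.total_residues, self.lam, self.kappa)
        rec = self.db[idx]
        return HomologyHit(
            query_id=query_id,
            subject_id=rec.id,
            frame=frame,
            raw_score=float(raw),
            bit_score=bit,
            e_value=e_value,
            percent_identity=identity,
            query_coverage=coverage,
            taxon_bin=rec.taxon_bin,
        )

    def search_many(self, items) -> dict[str, HomologyHit | None]:
        """Best hit per (id, sequence) pair."""
        return {qid: self.search(qid, s) for qid, s in items}


@dataclass
class BinResult:
    bins: dict[str, list] = field(default_factory=dict)  # taxon_bin -> items
    phix: list = field(default_factory=list)
    unassigned: list = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        out = {taxon: len(items) for taxon, items in sorted(self.bins.items())}
        out["phiX_removed"] = len(self.phix)
        out["unassigned"] = len(self.unassigned)
        return out

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.bins.values()) + len(self.phix) + len(self.unassigned)


def bin_reads(
    reads,
    hits: dict[str, HomologyHit | None],
    db_by_id: dict[str, ProteinRecord],
    threshold: float = E_VALUE_THRESHOLD,
) -> BinResult:
    """Assign reads to taxon bins by best hit (strict E < threshold).

    phiX-labeled subjects are tallied separately and excluded from every
    bin; reads with no hit or a hit at or above the threshold go to the
    unassigned pool.
    """
    result = BinResult()
    for read in reads:
        hit = hits.get(read.id)
        if hit is None or not hit.e_value < threshold:
            result.unassigned.append(read)
            continue
        if db_by_id[hit.subject_id].is_phix:
            result.phix.append(read)
            continue
        result.bins.setdefault(hit.taxon_bin, []).append(read)
    return result


# ---------------------------------------------------------------------------
# protein DB FASTA dialect: ">id taxon=...;species=...;genome_type=...;plant_host=yes"

def write_protein_db(records: list[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            parts = [f"taxon={rec.taxon_bin}", f"species={rec.species}"]
            if rec.genome_type:
                parts.append(f"genome_type={rec.genome_type}")
            if rec.plant_host:
                parts.append("plant_host=yes")
            fh.write(f">{rec.id} {';'.join(parts)}\n{rec.sequence}\n")


def load_protein_db(path) -> list[ProteinRecord]:
    from .seqtools import read_fasta

    records = []
    for name, desc, seq in read_fasta(path):
        fields = dict(part.split("=", 1) for part in desc.split(";") if "=" in part)
        records.append(
            ProteinRecord(
                id=name,
                sequence=seq,
                taxon_bin=fields.get("taxon", "Animal"),
                species=fields.get("species", ""),
                genome_type=fields.get("genome_type"),
                plant_host=fields.get("plant_host") == "yes",
            )
        )
    return records


def write_hits_tsv(hits: dict[str, HomologyHit | None], path) -> None:
    cols = (
        "query_id", "subject_id", "frame", "raw_score", "bit_score",
        "e_value", "percent_identity", "query_coverage", "taxon_bin",
    )
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for qid in sorted(hits):
            hit = hits[qid]
            if hit is None:
                continue
            fh.write(
                f"{hit.query_id}\t{hit.subject_id}\t{hit.frame}\t{hit.raw_score:g}\t"
                f"{hit.bit_score:.2f}\t{hit.e_value:.3g}\t{hit.percent_identity:.1f}\t"
                f"{hit.query_coverage:.1f}\t{hit.taxon_bin}\n"
            )
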
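"""Winnowing and prioritization of assembled virus sequences.

Stages: nucleotide matching against known virus genomes (>= 95%
identity over the aligned region, minimum aligned length 50 nt, matched
sequences binned by species and excluded), exclusion rules for the
remainder (no significant homology hit, < 100 nt, non-virus identity,
plant-virus identity), library-representation classification with
priority ranking, and exact-integer fraction summaries with half-up
decimal rounding.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

from Bio import Align

from .homology import E_VALUE_THRESHOLD, HomologyHit, ProteinRecord
from .seqtools import revcomp

KNOWN_IDENTITY_MIN = 95.0
KNOWN_ALIGNED_MIN = 50
LENGTH_MIN_NT = 100
VIRUS_BINS = frozenset({"NonPhageVirus", "Phage"})


@dataclass(frozen=True)
class KnownVirusMatch:
    query_id: str
    virus_species: str
    nucleotide_identity: float  # percent, >= KNOWN_IDENTITY_MIN for binned matches
    aligned_length: int


@dataclass(frozen=True)
class ContigCountRow:
    """Per-library singleton counts for one contig (a Table-2-style row)."""

    designation: str
    library_counts: tuple[int, ...]
    libraries: tuple[str, ...]
    size_nt: int
    singletons_total: int
    e_score: str = ""
    query_coverage: int | float | None = None
    identity: int | float | None = None
    species: str = ""
    genome_type: str = ""
    virus_family: str = ""

    def __post_init__(self):
        if sum(self.library_counts) != self.singletons_total:
            raise ValueError(
                f"{self.designation}: per-library counts sum to "
                f"{sum(self.library_counts)}, total says {self.singletons_total}"
            )


@dataclass(frozen=True)
class ProspectRecord:
    designation: str
    singleton_total: int
    library_counts: tuple[int, ...]
    libraries: tuple[str, ...]
    size_nt: int
    species: str
    e_score: str
    coverage_identity: str
    genome_type: str
    virus_family: str
    representation_class: str  # e.g. "4-of-4"
    libraries_represented: int
    rank: int
    high_likelihood: bool


def _nt_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def _aln_identity(alignment) -> tuple[float, int]:
    """Percent identity over aligned columns and the aligned column count."""
    t_blocks, q_blocks = alignment.aligned
    target, query = alignment.target, alignment.query
    matches = cols = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        cols += te - ts
        for a, b in zip(target[ts:te], query[qs:qe]):
            if a == b:
                matches += 1
    for i in range(1, len(t_blocks)):
        cols += t_blocks[i][0] - t_blocks[i - 1][1]
        cols += q_blocks[i][0] - q_blocks[i - 1][1]
    return (100.0 * matches / cols if cols else 0.0), cols


def _canonical_kmers(seq: str, k: int) -> set[str]:
    out = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        rc = revcomp(kmer)
        out.add(kmer if kmer <= rc else rc)
    return out


def match_known_viruses(
    sequences: list[tuple[str, str]],
    known_genomes: dict[str, str],
    min_identity: float = KNOWN_IDENTITY_MIN,
    min_aligned: int = KNOWN_ALIGNED_MIN,
    prefilter_k: int = 21,
) -> tuple[dict[str, list[KnownVirusMatch]], list[tuple[str, str]]]:
    """Bin sequences matching a known virus genome; return (bins, unmatched).

    A sequence matches when its best local nucleotide alignment (either
    strand) to any known genome reaches ``min_identity`` percent over at
    least ``min_aligned`` aligned columns. Shared-21-mer prefiltering
    skips hopeless genome comparisons; a sequence sharing no k-mer with
    a genome cannot reach 95% identity over 50 nt.
    """
    aligner = _nt_aligner()
    genome_kmers = {
        label: _canonical_kmers(genome, prefilter_k)
        for label, genome in known_genomes.items()
    }
    bins: dict[str, list[KnownVirusMatch]] = {label: [] for label in known_genomes}
    unmatched: list[tuple[str, str]] = []
    for qid, seq in sequences:
        q_kmers = _canonical_kmers(seq, prefilter_k)
        best: tuple[float, int, float, str] | None = None  # (score, cols, identity, label)
        for label in sorted(known_genomes):
            if not (q_kmers & genome_kmers[label]):
                continue
            genome = known_genomes[label]
            for strand_seq in (seq, revcomp(seq)):
                alns = aligner.align(strand_seq, genome)
                try:
                    top = alns[0]
                except IndexError:
                    continue
                identity, cols = _aln_identity(top)
                if cols < min_aligned or identity < min_identity:
                    continue
                cand = (float(top.score), cols, identity, label)
                if best is None or cand[:2] > best[:2]:
                    best = cand
        if best is None:
            unmatched.append((qid, seq))
        else:
            _, cols, identity, label = best
            bins[label].append(KnownVirusMatch(qid, label, identity, cols))
    return bins, unmatched


EXCLUSION_RULES = ("no_match", "short", "non_virus", "plant_virus")


def apply_exclusions(
    items: list[tuple[str, str]],
    rehits: dict[str, HomologyHit | None],
    db_by_id: dict[str, ProteinRecord],
    e_threshold: float = E_VALUE_THRESHOLD,
    min_length: int = LENGTH_MIN_NT,
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Exclude items with no significant hit, < ``min_length`` nt,
    non-virus identity, or plant-virus identity; returns (retained, tally)."""
    retained: list[tuple[str, str]] = []
    tally = {rule: 0 for rule in EXCLUSION_RULES}
    tally["retained"] = 0
    for qid, seq in items:
        hit = rehits.get(qid)
        if hit is None or not hit.e_value < e_threshold:
            tally["no_match"] += 1
        elif len(seq) < min_length:
            tally["short"] += 1
        elif hit.taxon_bin not in VIRUS_BINS:
            tally["non_virus"] += 1
        elif db_by_id[hit.subject_id].plant_host:
            tally["plant_virus"] += 1
        else:
            tally["retained"] += 1
            retained.append((qid, seq))
    return retained, tally


def classify_and_rank(rows: list[ContigCountRow]) -> list[ProspectRecord]:
    """Classify library representation and rank retained contigs.

    Records are sorted descending by singleton total, then libraries
    represented, then size; rank is 1-based over that order. Contigs
    represented in every library are flagged high-likelihood prospects.
    """
    for row in rows:
        if all(c == 0 for c in row.library_counts):
            raise ValueError(f"{row.designation}: contig with no member reads")
    n_libs_total = len(rows[0].library_counts) if rows else 0
    ordered = sorted(
        rows,
        key=lambda r: (
            -r.singletons_total,
            -sum(1 for c in r.library_counts if c > 0),
            -r.size_nt,
            r.designation,
        ),
    )
    records = []
    for rank, row in enumerate(ordered, 1):
        represented = sum(1 for c in row.library_counts if c > 0)
        cov = "" if row.query_coverage is None else f"{row.query_coverage:g}"
        ident = "" if row.identity is None else f"{row.identity:g}"
        records.append(
            ProspectRecord(
                designation=row.designation,
                singleton_total=row.singletons_total,
                library_counts=row.library_counts,
                libraries=row.libraries,
                size_nt=row.size_nt,
                species=row.species,
                e_score=row.e_score,
                coverage_identity=f"{cov}:{ident}" if (cov or ident) else "",
                genome_type=row.genome_type,
                virus_family=row.virus_family,
                representation_class=f"{represented}-of-{n_libs_total}",
                libraries_represented=represented,
                rank=rank,
                high_likelihood=represented == n_libs_total,
            )
        )
    return records


def class_summary(records: list[ProspectRecord]) -> dict[str, tuple[int, int]]:
    """Per representation class: (number of contigs, singleton sum)."""
    out: dict[str, tuple[int, int]] = {}
    for rec in records:
        n, s = out.get(rec.representation_class, (0, 0))
        out[rec.representation_class] = (n + 1, s + rec.singleton_total)
    return out


def pct(numerator: int, denominator: int, ndigits: int = 1) -> float | None:
    """Exact-ratio percentage, half-up rounded; None when undefined."""
    if denominator == 0:
        return None
    quantum = Decimal(1).scaleb(-ndigits)
    value = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        quantum, rounding=ROUND_HALF_UP
    )
    return float(value)


@dataclass
class FractionReport:
    """Fraction lines with exact integer numerators/denominators."""

    lines: list[tuple[str, int, int, float | None]] = field(default_factory=list)

    def add(self, label: str, numerator: int, denominator: int, ndigits: int = 1):
        self.lines.append((label, numerator, denominator, pct(numerator, denominator, ndigits)))

    def as_dict(self) -> dict[str, dict]:
        return {
            label: {"numerator": n, "denominator": d, "percent": p}
            for label, n, d, p in self.lines
        }


def summarize_fractions(counts: dict[str, int]) -> FractionReport:
    """Taxon/known-virus fraction report from integer tallies.

    Expected keys: ``non_host_total``, ``non_phage_virus``, optional
    per-bin ``bin_<taxon>`` counts, and per-species ``known_<species>``
    counts. Zero denominators yield undefined (None) percentages.
    """
    report = FractionReport()
    non_host = counts.get("non_host_total", 0)
    non_phage = counts.get("non_phage_virus", 0)
    report.add("non_phage_virus/non_host", non_phage, non_host)
    known_total = 0
    for key in sorted(counts):
        if key.startswith("known_"):
            known_total += counts[key]
    report.add("known_virus_matched/non_phage", known_total, non_phage)
    for key in sorted(counts):
        if key.startswith("known_"):
            report.add(f"{key}/non_phage", counts[key], non_phage)
        elif key.startswith("bin_"):
            report.add(f"{key}/non_host", counts[key], non_host)
    return report


# ---------------------------------------------------------------------------
# packaged fixtures transcribed from printed tables

def _fixture_text(name: str) -> str:
    return (resources.files("virowinnow.data") / name).read_text()


def load_table1() -> list[dict]:
    """Collection-site fixture: site, habitat, colony count, library label."""
    reader = csv.DictReader(_fixture_text("table1_colonies.tsv").splitlines(), delimiter="\t")
    rows = []
    for raw in reader:
        raw["n_colonies"] = int(raw["n_colonies"])
        rows.append(raw)
    return rows


def table1_library_sums() -> dict[str, int]:
    sums: dict[str, int] = {}
    for row in load_table1():
        sums[row["library"]] = sums.get(row["library"], 0) + row["n_colonies"]
    return sums


def load_table2() -> list[ContigCountRow]:
    """Contig-count fixture: 38 contigs with per-library singleton counts."""
    reader = csv.DictReader(_fixture_text("table2_contigs.tsv").splitlines(), delimiter="\t")
    libs = ("SAL_1", "SAL_2", "SAL_3", "SAL_4")
    rows = []
    for raw in reader:
        rows.append(
            ContigCountRow(
                designation=raw["designation"],
                library_counts=tuple(int(raw[lib]) for lib in libs),
                libraries=libs,
                size_nt=int(raw["size_nt"]),
                singletons_total=int(raw["singletons_total"]),
                e_score=raw["e_score"],
                query_coverage=int(raw["query_coverage_pct"]),
                identity=int(raw["identity_pct"]),
                species=raw["best_hit_species"],
                genome_type=raw["genome_type"],
                virus_family=raw["virus_family"],
            )
        )
    return rows


def load_fig2_counts() -> dict[str, int]:
    """Printed sequencing tallies used by the fraction summary."""
    out = {}
    for line in _fixture_text("fig2_counts.tsv").splitlines()[1:]:
        key, count = line.split("\t")
        out[key] = int(count)
    return out


def write_prospect_tsv(records: list[ProspectRecord], path) -> None:
    with open(path, "w") as fh:
        libs = records[0].libraries if records else ()
        lib_cols = "\t".join(libs)
        fh.write(
            "designation\tsingleton_total\tsize_nt\te_score\tcoverage:identity\t"
            f"best_hit_species\t{lib_cols}\tgenome_type\tvirus_family\t"
            "representation_class\trank\thigh_likelihood\n"
        )
        for r in records:
            counts = "\t".join(str(c) for c in r.library_counts)
            fh.write(
                f"{r.designation}\t{r.singleton_total}\t{r.size_nt}\t{r.e_score}\t"
                f"{r.coverage_identity}\t{r.species}\t{counts}\t{r.genome_type}\t"
                f"{r.virus_family}\t{r.representation_class}\t{r.rank}\t"
                f"{str(r.high_likelihood).lower()}\n"
            )
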
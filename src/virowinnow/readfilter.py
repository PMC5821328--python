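"""Quality filtering and host subtraction.

A read is retained iff its median Phred score is >= 20 and its length is
>= 25 (even-length medians are the mean of the two central values). Host
subtraction classifies a read as host-matched when it shares at least
``min_shared`` exact k-mers (either strand) with the host reference; the
unmatched pool flows downstream with library labels preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqtools import revcomp

QUALITY_MEDIAN_MIN = 20.0
LENGTH_MIN = 25
HOST_KMER_SIZE = 21
HOST_MIN_SHARED = 5


@dataclass
class Read:
    """One sequencing read with per-base qualities and a library label."""

    id: str
    sequence: str
    qualities: list[int]
    library: str

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )


@dataclass
class FilterTally:
    retained: int = 0
    rejected_median: int = 0
    rejected_length: int = 0
    rejected_empty: int = 0

    @property
    def total(self) -> int:
        return self.retained + self.rejected_median + self.rejected_length + self.rejected_empty


def median_phred(qualities: list[int]) -> float:
    """Median with the even-length convention: mean of the two central values."""
    n = len(qualities)
    if n == 0:
        raise ValueError("empty quality list")
    s = sorted(qualities)
    mid = n // 2
    if n % 2 == 1:
        return float(s[mid])
    return (s[mid - 1] + s[mid]) / 2.0


def quality_filter(reads) -> tuple[list[Read], FilterTally]:
    """Retain reads with median Phred >= 20 and length >= 25.

    Empty reads are rejected and counted separately; the length rule is
    checked before the median rule.
    """
    kept: list[Read] = []
    tally = FilterTally()
    for read in reads:
        if len(read.sequence) == 0:
            tally.rejected_empty += 1
        elif len(read.sequence) < LENGTH_MIN:
            tally.rejected_length += 1
        elif median_phred(read.qualities) < QUALITY_MEDIAN_MIN:
            tally.rejected_median += 1
        else:
            tally.retained += 1
            kept.append(read)
    return kept, tally


class HostIndex:
    """Set of canonical k-mers of a host reference (both strands, no N)."""

    def __init__(self, host_sequences, k: int = HOST_KMER_SIZE):
        self.k = k
        kmers: set[str] = set()
        if isinstance(host_sequences, str):
            host_sequences = [host_sequences]
        for seq in host_sequences:
            seq = seq.upper()
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                rc = revcomp(kmer)
                kmers.add(kmer if kmer <= rc else rc)
        self.kmers = kmers

    def shared_kmers(self, sequence: str) -> int:
        k = self.k
        seen = 0
        seq = sequence.upper()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            rc = revcomp(kmer)
            if (kmer if kmer <= rc else rc) in self.kmers:
                seen += 1
        return seen


@dataclass
class SubtractionTally:
    host_matched: int = 0
    unmatched: int = 0
    too_short: int = 0  # shorter than k: unmatched by definition (also in unmatched)


def subtract_host(
    reads,
    host_index: HostIndex,
    min_shared: int = HOST_MIN_SHARED,
) -> tuple[list[Read], list[Read], SubtractionTally]:
    """Partition reads into (host_matched, unmatched) by shared k-mer count."""
    matched: list[Read] = []
    unmatched: list[Read] = []
    tally = SubtractionTally()
    for read in reads:
        if len(read.sequence) < host_index.k:
            tally.too_short += 1
            tally.unmatched += 1
            unmatched.append(read)
        elif host_index.shared_kmers(read.sequence) >= min_shared:
            tally.host_matched += 1
            matched.append(read)
        else:
            tally.unmatched += 1
            unmatched.append(read)
    return matched, unmatched, tally


def parse_fastq(path, library: str) -> list[Read]:
    """Parse a Sanger (Phred+33) FASTQ file into labeled reads."""
    reads: list[Read] = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            fh.readline()  # separator
            qual = fh.readline().rstrip("\n")
            reads.append(
                Read(header[1:].split()[0], seq, [ord(c) - 33 for c in qual], library)
            )
    return reads


def write_unmatched_fasta(reads: list[Read], path) -> None:
    """The downstream conversion step: unmatched reads as FASTA (library in defline)."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.id} library={r.library}\n{r.sequence}\n")


def write_filter_tally(tally: FilterTally, sub: SubtractionTally, path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tcount\n")
        fh.write(f"input\t{tally.total}\n")
        fh.write(f"quality_retained\t{tally.retained}\n")
        fh.write(f"rejected_median\t{tally.rejected_median}\n")
        fh.write(f"rejected_length\t{tally.rejected_length}\n")
        fh.write(f"rejected_empty\t{tally.rejected_empty}\n")
        fh.write(f"host_matched\t{sub.host_matched}\n")
        fh.write(f"host_unmatched\t{sub.unmatched}\n")
        fh.write(f"shorter_than_k\t{sub.too_short}\n")
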
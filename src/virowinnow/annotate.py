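"""Dicistrovirus genome annotation.

ORF calling on the plus strand, architecture classification (two major
in-frame non-overlapping ORFs with flanking/intervening untranslated
regions and an optional short overlapping ORF at the 5' end of ORF2),
motif-based domain localization, polyA detection, and in-silico
replicative-strand accounting.

Coordinates are 0-based half-open internally; the GFF3 writer emits
1-based inclusive spans.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

from .seqtools import CODON_TABLE

MAJOR_ORF_MIN_NT = 600
ORFX_MIN_NT = 60
ORFX_WINDOW_NT = 200
UTR_MIN_NT = 10

MOTIF_SCORE_FIXED = 2
MOTIF_SCORE_CLASS = 1


@dataclass(frozen=True)
class Orf:
    """An ATG-initiated open reading frame on the plus strand.

    ``end`` includes the terminating stop codon when one exists.
    """

    start: int
    end: int
    frame: int  # 1..3, i.e. start % 3 + 1
    translation: str  # stop symbol excluded

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DomainRegion:
    name: str
    pfam: str
    orf_start: int  # start of the host ORF (genome coords)
    span: tuple[int, int]  # genome coords, 0-based half-open
    score: int
    expected_orf: str  # "orf1" / "orf2" per the motif library
    in_expected_orf: bool


@dataclass
class GenomeAnnotation:
    genome_id: str
    length: int
    orfs: list[Orf]
    architecture_class: str
    evidence: list[tuple[str, bool, str]]
    orfx_present: bool
    domains: list[DomainRegion]
    polya: bool
    plus_strand_reads: int = 0
    minus_strand_reads: int = 0
    replicative: bool = False


class Motif:
    """A short position-specific amino-acid pattern with integer scoring.

    Pattern tokens: an uppercase residue scores +2 on match, a residue
    class ``[XYZ]`` scores +1, and ``x`` is a free position. The best
    window at or above ``threshold`` is reported.
    """

    def __init__(self, name: str, pfam: str, expected_orf: str, pattern: str, threshold: int):
        self.name = name
        self.pfam = pfam
        self.expected_orf = expected_orf
        self.pattern = pattern
        self.threshold = threshold
        self.tokens: list[tuple[str, str]] = []
        i = 0
        while i < len(pattern):
            ch = pattern[i]
            if ch == "[":
                j = pattern.index("]", i)
                self.tokens.append(("class", pattern[i + 1 : j]))
                i = j + 1
            elif ch == "x":
                self.tokens.append(("any", ""))
                i += 1
            else:
                self.tokens.append(("fixed", ch))
                i += 1

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def max_score(self) -> int:
        return sum(
            MOTIF_SCORE_FIXED if kind == "fixed" else MOTIF_SCORE_CLASS if kind == "class" else 0
            for kind, _ in self.tokens
        )

    def consensus(self, filler: str = "A") -> str:
        """A maximally scoring instance of the pattern (free positions -> filler)."""
        out = []
        for kind, res in self.tokens:
            if kind == "fixed":
                out.append(res)
            elif kind == "class":
                out.append(res[0])
            else:
                out.append(filler)
        return "".join(out)

    def score_window(self, window: str) -> int:
        s = 0
        for (kind, res), aa in zip(self.tokens, window):
            if kind == "fixed" and aa == res:
                s += MOTIF_SCORE_FIXED
            elif kind == "class" and aa in res:
                s += MOTIF_SCORE_CLASS
        return s

    def best_match(self, protein: str) -> tuple[int, int] | None:
        """Best ``(score, start)`` window, or None if the protein is too short."""
        w = len(self.tokens)
        if len(protein) < w:
            return None
        best = (-1, 0)
        for i in range(len(protein) - w + 1):
            s = self.score_window(protein[i : i + w])
            if s > best[0]:
                best = (s, i)
        return best


def load_motif_library(path=None) -> list[Motif]:
    """Load the packaged motif library (or a user TSV with the same columns)."""
    if path is None:
        ref = resources.files("virowinnow.data") / "motifs.tsv"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    motifs = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    for line in lines[1:]:
        name, pfam, expected_orf, pattern, threshold = line.split("\t")
        motifs.append(Motif(name, pfam, expected_orf, pattern, int(threshold)))
    return motifs


def find_orfs(genome: str, min_length: int = ORFX_MIN_NT) -> list[Orf]:
    """All ATG-initiated plus-strand ORFs of at least ``min_length`` nt.

    Every qualifying ATG opens an ORF, so ORFs sharing a stop codon are
    nested; use :func:`maximal_orfs` to reduce to the longest per stop.
    An ORF reaching the end of the sequence without a stop is reported
    (trailing partial codon dropped).
    """
    n = len(genome)
    orfs: list[Orf] = []
    for offset in range(3):
        starts: list[int] = []
        i = offset
        while i + 3 <= n:
            codon = genome[i : i + 3]
            aa = CODON_TABLE.get(codon, "X")
            if codon == "ATG":
                starts.append(i)
            if aa == "*":
                for s in starts:
                    end = i + 3
                    if end - s >= min_length:
                        orfs.append(
                            Orf(s, end, offset + 1, _translate_span(genome, s, end - 3))
                        )
                starts = []
            i += 3
        # open ORFs running to the end of the readable frame
        for s in starts:
            end = i  # last full codon boundary in this frame
            if end - s >= min_length:
                orfs.append(Orf(s, end, offset + 1, _translate_span(genome, s, end)))
    orfs.sort(key=lambda o: (o.start, o.end))
    return orfs


def _translate_span(genome: str, start: int, end: int) -> str:
    return "".join(
        CODON_TABLE.get(genome[i : i + 3], "X") for i in range(start, end, 3)
    )


def maximal_orfs(orfs: list[Orf]) -> list[Orf]:
    """Longest ORF per (frame, stop position): collapses nested ATG starts."""
    best: dict[tuple[int, int], Orf] = {}
    for o in orfs:
        key = (o.frame, o.end)
        if key not in best or o.length > best[key].length:
            best[key] = o
    return sorted(best.values(), key=lambda o: (o.start, o.end))


def classify_architecture(
    genome: str,
    orfs: list[Orf],
    major_min: int = MAJOR_ORF_MIN_NT,
    orfx_min: int = ORFX_MIN_NT,
    orfx_window: int = ORFX_WINDOW_NT,
    utr_min: int = UTR_MIN_NT,
) -> tuple[str, list[tuple[str, bool, str]], bool]:
    """Classify a genome as "dicistrovirus-like" or "other".

    Returns ``(architecture_class, evidence, orfx_present)`` where
    evidence is a list of ``(clause, satisfied, detail)``. The class is
    "dicistrovirus-like" iff every clause holds: exactly two major ORFs
    (>= ``major_min`` nt, nested starts collapsed), non-overlapping, in
    the same reading frame, with 5'UTR / intergenic region / 3'UTR each
    >= ``utr_min`` nt. The ORFx flag is set when an extra ORF of
    >= ``orfx_min`` nt overlaps the first ``orfx_window`` nt of ORF2 in
    a different frame; it does not affect the class.
    """
    maximal = maximal_orfs(orfs)
    majors = sorted((o for o in maximal if o.length >= major_min), key=lambda o: o.start)
    evidence: list[tuple[str, bool, str]] = []

    two = len(majors) == 2
    evidence.append(("two_major_orfs", two, f"{len(majors)} ORF(s) >= {major_min} nt"))
    orfx_present = False
    if not two:
        return "other", evidence, orfx_present

    orf1, orf2 = majors
    non_overlap = orf1.end <= orf2.start
    evidence.append(
        ("non_overlapping", non_overlap, f"ORF1 ends {orf1.end}, ORF2 starts {orf2.start}")
    )
    utr5 = orf1.start
    igr = orf2.start - orf1.end
    utr3 = len(genome) - orf2.end
    evidence.append(("utr5", utr5 >= utr_min, f"{utr5} nt"))
    evidence.append(("igr", igr >= utr_min, f"{igr} nt"))
    evidence.append(("utr3", utr3 >= utr_min, f"{utr3} nt"))
    in_frame = orf1.start % 3 == orf2.start % 3
    evidence.append(
        ("in_frame", in_frame, f"starts {orf1.start} and {orf2.start} (mod 3)")
    )

    window_end = orf2.start + orfx_window
    for o in maximal:
        if o in majors or o.length < orfx_min:
            continue
        if o.frame != orf2.frame and o.start < window_end and o.end > orf2.start:
            orfx_present = True
            break

    ok = all(flag for _, flag, _ in evidence)
    return ("dicistrovirus-like" if ok else "other"), evidence, orfx_present


def locate_domains(orfs: list[Orf], motifs: list[Motif]) -> list[DomainRegion]:
    """Best motif spans per (motif, ORF) at or above each motif threshold.

    ORF order determines the orf1/orf2 labels used for the
    expected-location check (violations are reported, never fatal).
    """
    regions: list[DomainRegion] = []
    ordered = sorted(orfs, key=lambda o: o.start)
    for motif in motifs:
        for idx, orf in enumerate(ordered):
            hit = motif.best_match(orf.translation)
            if hit is None or hit[0] < motif.threshold:
                continue
            score, aa_start = hit
            g_start = orf.start + 3 * aa_start
            g_end = g_start + 3 * len(motif)
            label = f"orf{idx + 1}"
            regions.append(
                DomainRegion(
                    name=motif.name,
                    pfam=motif.pfam,
                    orf_start=orf.start,
                    span=(g_start, g_end),
                    score=score,
                    expected_orf=motif.expected_orf,
                    in_expected_orf=(label == motif.expected_orf),
                )
            )
    return regions


def detect_polya(genome: str, min_run: int = 10) -> bool:
    """True iff the 3' terminus ends in at least ``min_run`` consecutive A."""
    run = 0
    for base in reversed(genome):
        if base == "A":
            run += 1
            if run >= min_run:
                return True
        else:
            break
    return run >= min_run


def strand_accounting(strand_tags, min_minus: int = 5) -> tuple[int, int, bool]:
    """Tally plus/minus read strands; replicative iff minus count >= ``min_minus``.

    This is the in-silico analog of a strand-specific RT-PCR assay for
    the replicative strand of a positive-sense RNA virus.
    """
    plus = minus = 0
    for tag in strand_tags:
        if tag == "+":
            plus += 1
        elif tag == "-":
            minus += 1
        else:
            raise ValueError(f"strand tag must be '+' or '-', got {tag!r}")
    return plus, minus, minus >= min_minus


def annotate_genome(
    genome_id: str,
    genome: str,
    motifs: list[Motif] | None = None,
    strand_tags=None,
    min_orf: int = ORFX_MIN_NT,
    major_min: int = MAJOR_ORF_MIN_NT,
    min_minus: int = 5,
) -> GenomeAnnotation:
    """Run the full annotation suite on one assembled genome."""
    if motifs is None:
        motifs = load_motif_library()
    orfs = find_orfs(genome, min_length=min_orf)
    arch, evidence, orfx = classify_architecture(genome, orfs, major_min=major_min)
    majors = sorted(
        (o for o in maximal_orfs(orfs) if o.length >= major_min), key=lambda o: o.start
    )
    domains = locate_domains(majors, motifs)
    plus = minus = 0
    replicative = False
    if strand_tags is not None:
        plus, minus, replicative = strand_accounting(strand_tags, min_minus=min_minus)
    return GenomeAnnotation(
        genome_id=genome_id,
        length=len(genome),
        orfs=majors,
        architecture_class=arch,
        evidence=evidence,
        orfx_present=orfx,
        domains=domains,
        polya=detect_polya(genome),
        plus_strand_reads=plus,
        minus_strand_reads=minus,
        replicative=replicative,
    )


def write_gff3(ann: GenomeAnnotation, path) -> None:
    """Write the annotation as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {ann.genome_id} 1 {ann.length}\n")
        for i, orf in enumerate(ann.orfs, 1):
            fh.write(
                f"{ann.genome_id}\tvirowinnow\tCDS\t{orf.start + 1}\t{orf.end}\t.\t+\t0\t"
                f"ID=orf{i};Name=ORF{i}\n"
            )
        for d in ann.domains:
            fh.write(
                f"{ann.genome_id}\tvirowinnow\tmisc_feature\t{d.span[0] + 1}\t{d.span[1]}\t"
                f"{d.score}\t+\t.\tName={d.name};pfam={d.pfam};"
                f"expected={d.expected_orf};in_expected_orf={str(d.in_expected_orf).lower()}\n"
            )
        if ann.polya:
            fh.write(
                f"{ann.genome_id}\tvirowinnow\tpolyA_site\t{ann.length}\t{ann.length}\t.\t+\t.\t"
                f"Name=polyA\n"
            )


def evidence_report(ann: GenomeAnnotation) -> str:
    """JSON evidence report for one annotated genome."""
    return json.dumps(
        {
            "genome_id": ann.genome_id,
            "length": ann.length,
            "architecture_class": ann.architecture_class,
            "orfx_present": ann.orfx_present,
            "polya": ann.polya,
            "orfs": [
                {"start": o.start, "end": o.end, "frame": o.frame, "length": o.length}
                for o in ann.orfs
            ],
            "evidence": [
                {"clause": c, "satisfied": ok, "detail": d} for c, ok, d in ann.evidence
            ],
            "domains": [
                {
                    "name": d.name,
                    "pfam": d.pfam,
                    "span": list(d.span),
                    "score": d.score,
                    "in_expected_orf": d.in_expected_orf,
                }
                for d in ann.domains
            ],
            "plus_strand_reads": ann.plus_strand_reads,
            "minus_strand_reads": ann.minus_strand_reads,
            "replicative": ann.replicative,
        },
        indent=2,
    )
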
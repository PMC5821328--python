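"""Synthetic four-library metavirome generation with a ground-truth manifest.

The generator emulates the statistical structure the downstream analysis
assumes: host transcripts dominating each library, known viruses at
library-varying abundance, one planted novel dicistrovirus that is
actively replicating (a configurable fraction of its reads come from the
minus strand), phage/phiX-like internal-control reads, and
plant/fungal/bacterial/animal decoys.

Randomness: one seeded :class:`numpy.random.Generator` is threaded
through all draws. Draw order: host genome, novel-virus genome (with
bounded rejection sampling so the planted architecture verifies), known
viruses in listed order, decoys in fixed order, then per library and per
source each read's start / strand / errors / qualities.

Single-end reads only; the downstream rules all operate per read.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

from . import annotate
from .homology import ProteinRecord
from .readfilter import Read
from .seqtools import (
    random_dna,
    random_protein,
    reverse_translate,
    revcomp,
    translate,
    write_fasta,
)


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass(frozen=True)
class NovelVirusSpec:
    """Geometry of the planted dicistrovirus genome (all lengths in nt)."""

    orf1_nt: int = 1500
    orf2_nt: int = 900
    orfx_nt: int = 90
    utr5_nt: int = 50
    igr_nt: int = 150
    utr3_nt: int = 60
    polya_nt: int = 20

    def validate(self) -> None:
        for name in ("orf1_nt", "orf2_nt", "orfx_nt"):
            v = getattr(self, name)
            if v <= 0 or v % 3 != 0:
                raise ConfigError(f"{name} must be a positive multiple of 3, got {v}")
        for name in ("utr5_nt", "igr_nt", "utr3_nt"):
            if getattr(self, name) < 10:
                raise ConfigError(f"{name} must be >= 10 nt")
        if self.igr_nt % 3 != 0:
            raise ConfigError("igr_nt must be a multiple of 3 so ORF1/ORF2 stay in frame")
        if self.polya_nt < 10:
            raise ConfigError("polya_nt must be >= 10 nt for polyA detection")
        if self.orfx_nt + 13 > self.orf2_nt:
            raise ConfigError("orfx_nt does not fit inside ORF2")

    @property
    def genome_length(self) -> int:
        return (
            self.utr5_nt + self.orf1_nt + self.igr_nt + self.orf2_nt
            + self.utr3_nt + self.polya_nt
        )


@dataclass(frozen=True)
class SourceSpec:
    """One read source: a genome with a taxonomic identity."""

    name: str
    taxon_bin: str
    species: str
    genome_type: str | None = None  # virus records only
    replicating: bool = False  # minus-strand reads are drawn for these
    plant_host: bool = False  # plant-infecting virus flag


# fixed decoy roster (coding genomes so translated search finds them)
DECOY_SOURCES: tuple[SourceSpec, ...] = (
    SourceSpec("phage", "Phage", "Simulated microvirus", genome_type="ssDNA"),
    SourceSpec("phiX", "Phage", "Enterobacteria phage phiX174", genome_type="ssDNA"),
    SourceSpec("plant", "Plant", "Simulated grass transcript"),
    SourceSpec("fungi", "Fungi", "Simulated yeast transcript"),
    SourceSpec("bacteria", "Bacteria", "Simulated soil bacterium transcript"),
    SourceSpec("animal", "Animal", "Simulated host-like transcript"),
    SourceSpec(
        "plant_virus", "NonPhageVirus", "Simulated plant virus",
        genome_type="ssRNA", plant_host=True,
    ),
)

DECOY_GENOME_NT = 1200

DEFAULT_KNOWN_VIRUSES: tuple[tuple[str, int], ...] = (
    ("SINV-1", 1800),
    ("SINV-2", 1500),
    ("SINV-3", 1500),
    ("SINV-4", 1800),
    ("SiDNV", 1500),
)

#: per-library abundance deltas applied to the base row (known viruses vary
#: by library, host absorbs the difference) — emulates geographic variation
_BASE_ABUNDANCE = {
    "novel_virus": 0.05,
    "SINV-1": 0.05,
    "SINV-2": 0.02,
    "SINV-3": 0.002,
    "SINV-4": 0.04,
    "SiDNV": 0.001,
    "phage": 0.03,
    "phiX": 0.02,
    "plant": 0.025,
    "fungi": 0.015,
    "bacteria": 0.012,
    "animal": 0.02,
    "plant_virus": 0.015,
}

_LIBRARY_DELTAS = (
    {},
    {"SINV-1": +0.02, "SINV-2": -0.01, "SINV-4": -0.02},
    {"SINV-1": -0.03, "SINV-2": +0.02, "SINV-4": +0.01},
    {"SINV-1": +0.01, "SINV-2": -0.015, "SINV-4": +0.02},
)


def default_abundance_matrix(n_libraries: int = 4) -> dict[str, dict[str, float]]:
    """Default per-library abundance rows (host absorbs the remainder)."""
    rows: dict[str, dict[str, float]] = {}
    for i in range(n_libraries):
        deltas = _LIBRARY_DELTAS[i % len(_LIBRARY_DELTAS)]
        row = dict(_BASE_ABUNDANCE)
        for key, d in deltas.items():
            row[key] = round(row[key] + d, 6)
        row["host"] = round(1.0 - sum(row.values()), 6)
        rows[f"SAL_{i + 1}"] = row
    return rows


@dataclass
class SimConfig:
    n_libraries: int = 4
    reads_per_library: int = 2000
    read_length: int = 150
    host_genome_length: int = 20000
    known_virus_set: tuple[tuple[str, int], ...] = DEFAULT_KNOWN_VIRUSES
    novel_virus: NovelVirusSpec = field(default_factory=NovelVirusSpec)
    abundance_matrix: dict[str, dict[str, float]] | None = None
    minus_strand_fraction: float = 0.1
    substitution_error_rate: float = 0.005
    quality_median: int = 32
    quality_sd: float = 4.0
    seed: int = 0

    @property
    def libraries(self) -> list[str]:
        return [f"SAL_{i + 1}" for i in range(self.n_libraries)]

    def resolved_abundance(self) -> dict[str, dict[str, float]]:
        if self.abundance_matrix is not None:
            return self.abundance_matrix
        return default_abundance_matrix(self.n_libraries)

    def validate(self) -> None:
        if self.n_libraries < 1:
            raise ConfigError("n_libraries must be >= 1")
        if self.reads_per_library < 1:
            raise ConfigError("reads_per_library must be >= 1")
        if self.read_length < 1 or self.host_genome_length < 1:
            raise ConfigError("lengths must be positive")
        if not 0.0 <= self.minus_strand_fraction <= 1.0:
            raise ConfigError("minus_strand_fraction must be in [0, 1]")
        if not 0.0 <= self.substitution_error_rate < 1.0:
            raise ConfigError("substitution_error_rate must be in [0, 1)")
        self.novel_virus.validate()
        for label, length in self.known_virus_set:
            if length < 200:
                raise ConfigError(f"known virus {label} genome too short ({length} nt)")
        abundance = self.resolved_abundance()
        known_labels = {label for label, _ in self.known_virus_set}
        valid = {"host", "novel_virus"} | known_labels | {s.name for s in DECOY_SOURCES}
        for lib in self.libraries:
            if lib not in abundance:
                raise ConfigError(f"abundance matrix missing library {lib}")
            row = abundance[lib]
            unknown = set(row) - valid
            if unknown:
                raise ConfigError(f"abundance row {lib} has unknown sources {sorted(unknown)}")
            total = sum(row.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"abundance row {lib} sums to {total!r}, expected 1")
            if any(v < 0 for v in row.values()):
                raise ConfigError(f"abundance row {lib} has negative entries")


@dataclass
class ReferenceSet:
    """Reference sequences + the protein database built for one config."""

    host_genome: str
    novel_genome: str
    novel_layout: dict
    known_genomes: dict[str, str]
    decoy_genomes: dict[str, str]
    proteins: list[ProteinRecord]
    sources: dict[str, SourceSpec]

    def genome_for(self, source: str) -> str:
        if source == "host":
            return self.host_genome
        if source == "novel_virus":
            return self.novel_genome
        if source in self.known_genomes:
            return self.known_genomes[source]
        return self.decoy_genomes[source]


@dataclass(frozen=True)
class ManifestEntry:
    read_id: str
    library: str
    source: str
    genome: str
    strand: str  # '+' or '-'
    start: int  # 0-based on the source genome forward strand


def _dna_without_atg(length: int, rng: np.random.Generator) -> str:
    """Random DNA with every ATG occurrence broken (T -> C)."""
    seq = random_dna(length, rng)
    while "ATG" in seq:
        seq = seq.replace("ATG", "ACG")
    return seq


def _plant(protein: str, motif_consensus: str, aa_offset: int) -> str:
    end = aa_offset + len(motif_consensus)
    if end > len(protein):
        raise ConfigError("motif does not fit in ORF; increase the ORF length")
    return protein[:aa_offset] + motif_consensus + protein[end:]


def _build_novel_genome(
    spec: NovelVirusSpec, motifs: list[annotate.Motif], rng: np.random.Generator
) -> tuple[str, dict]:
    """Construct a genome satisfying the dicistrovirus architecture contract.

    Uses bounded rejection sampling: the candidate is re-drawn until the
    annotation module verifies the planted ORFs, class, and ORFx flag.
    """
    by_name = {m.name: m for m in motifs}
    orf1_aa = spec.orf1_nt // 3 - 1
    orf2_aa = spec.orf2_nt // 3 - 1

    for _ in range(100):
        prot1 = random_protein(orf1_aa, rng, start_met=True)
        # non-structural order: helicase, peptidase, RdRp (5' -> 3')
        prot1 = _plant(prot1, by_name["helicase"].consensus(), 20)
        prot1 = _plant(prot1, by_name["peptidase"].consensus(), orf1_aa // 2)
        rdrp = by_name["rdrp"].consensus()
        prot1 = _plant(prot1, rdrp, orf1_aa - len(rdrp) - 20)
        orf1_seq = reverse_translate(prot1, rng) + "TAA"

        prot2 = random_protein(orf2_aa, rng, start_met=True)
        capsid = by_name["capsid"].consensus()
        capsid_at = max((10 + spec.orfx_nt) // 3 + 4, orf2_aa // 2)
        prot2 = _plant(prot2, capsid, capsid_at)
        orf2_seq = reverse_translate(prot2, rng) + "TAA"

        # overlapping ORFx: patched at +10 nt into ORF2 (frame shift of 1)
        orfx_rel = 10
        orfx_body = reverse_translate(random_protein(spec.orfx_nt // 3 - 2, rng), rng)
        orfx_seq = "ATG" + orfx_body + "TAA"
        orf2_seq = (
            orf2_seq[:orfx_rel] + orfx_seq + orf2_seq[orfx_rel + spec.orfx_nt :]
        )
        # the patch must not truncate ORF2: reject if it introduced a stop
        if "*" in translate(orf2_seq[:-3]):
            continue

        utr5 = _dna_without_atg(spec.utr5_nt, rng)
        igr = _dna_without_atg(spec.igr_nt, rng)
        utr3 = _dna_without_atg(spec.utr3_nt, rng)
        genome = utr5 + orf1_seq + igr + orf2_seq + utr3 + "A" * spec.polya_nt

        orf1_start = spec.utr5_nt
        orf2_start = orf1_start + spec.orf1_nt + spec.igr_nt
        orfx_start = orf2_start + orfx_rel
        layout = {
            "orf1": (orf1_start, orf1_start + spec.orf1_nt),
            "orf2": (orf2_start, orf2_start + spec.orf2_nt),
            "orfx": (orfx_start, orfx_start + spec.orfx_nt),
            "orf1_protein": translate(genome[orf1_start : orf1_start + spec.orf1_nt - 3]),
            "orf2_protein": translate(genome[orf2_start : orf2_start + spec.orf2_nt - 3]),
            "orfx_protein": translate(genome[orfx_start : orfx_start + spec.orfx_nt - 3]),
        }

        # verify against the annotation contract before accepting
        orfs = annotate.find_orfs(genome, min_length=annotate.ORFX_MIN_NT)
        spans = {(o.start, o.end) for o in orfs}
        if not all(layout[k] in spans for k in ("orf1", "orf2", "orfx")):
            continue
        arch, _, orfx_flag = annotate.classify_architecture(genome, orfs)
        if arch != "dicistrovirus-like" or not orfx_flag:
            continue
        return genome, layout

    raise RuntimeError("failed to construct a verifying novel-virus genome")


def _build_coding_genome(
    total_nt: int,
    rng: np.random.Generator,
    polya: int = 0,
    utr: int = 20,
) -> tuple[str, str]:
    """A simple single-ORF genome of exactly ``total_nt`` nt; returns (genome, protein)."""
    body = total_nt - 2 * utr - polya
    orf_nt = (body // 3) * 3
    pad = body - orf_nt
    protein = random_protein(orf_nt // 3 - 1, rng, start_met=True)
    genome = (
        _dna_without_atg(utr, rng)
        + reverse_translate(protein, rng)
        + "TAA"
        + _dna_without_atg(utr + pad, rng)
        + "A" * polya
    )
    assert len(genome) == total_nt
    return genome, protein


def build_references(config: SimConfig) -> ReferenceSet:
    """Build host/known-virus/novel-virus references and the labeled protein DB."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    motifs = annotate.load_motif_library()

    host_genome = random_dna(config.host_genome_length, rng)
    novel_genome, layout = _build_novel_genome(config.novel_virus, motifs, rng)

    known_genomes: dict[str, str] = {}
    proteins: list[ProteinRecord] = [
        ProteinRecord(
            "novel_orf1", layout["orf1_protein"], "NonPhageVirus",
            "Novel dicistrovirus", genome_type="ssRNA",
        ),
        ProteinRecord(
            "novel_orf2", layout["orf2_protein"], "NonPhageVirus",
            "Novel dicistrovirus", genome_type="ssRNA",
        ),
    ]
    sources: dict[str, SourceSpec] = {
        "host": SourceSpec("host", "Animal", "Host (reference genome)"),
        "novel_virus": SourceSpec(
            "novel_virus", "NonPhageVirus", "Novel dicistrovirus",
            genome_type="ssRNA", replicating=True,
        ),
    }

    for label, length in config.known_virus_set:
        is_dna = label.endswith("DNV")
        genome, protein = _build_coding_genome(
            length, rng, polya=0 if is_dna else 15
        )
        known_genomes[label] = genome
        gtype = "ssDNA" if is_dna else "ssRNA"
        proteins.append(
            ProteinRecord(f"{label}_orf", protein, "NonPhageVirus", label, genome_type=gtype)
        )
        sources[label] = SourceSpec(
            label, "NonPhageVirus", label, genome_type=gtype,
            replicating=not is_dna,
        )

    decoy_genomes: dict[str, str] = {}
    for decoy in DECOY_SOURCES:
        genome, protein = _build_coding_genome(DECOY_GENOME_NT, rng)
        decoy_genomes[decoy.name] = genome
        proteins.append(
            ProteinRecord(
                f"{decoy.name}_protein", protein, decoy.taxon_bin, decoy.species,
                genome_type=decoy.genome_type, plant_host=decoy.plant_host,
            )
        )
        sources[decoy.name] = decoy

    return ReferenceSet(
        host_genome=host_genome,
        novel_genome=novel_genome,
        novel_layout=layout,
        known_genomes=known_genomes,
        decoy_genomes=decoy_genomes,
        proteins=proteins,
        sources=sources,
    )


_QUAL_CLIP = (2, 40)


def _draw_qualities(n: int, median: int, sd: float, rng: np.random.Generator) -> list[int]:
    q = np.rint(rng.normal(median, sd, n)).astype(int)
    return list(np.clip(q, *_QUAL_CLIP))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.shape[0]) < rate
    if not hit.any():
        return seq
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    idx = np.nonzero(hit)[0]
    for i in idx:
        current = arr[i]
        choices = bases[bases != current]
        arr[i] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode("ascii")


def simulate_reads(
    config: SimConfig, refs: ReferenceSet
) -> tuple[dict[str, list[Read]], list[ManifestEntry]]:
    """Draw per-library reads (multinomial over the abundance row) + manifest."""
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    abundance = config.resolved_abundance()
    reads: dict[str, list[Read]] = {}
    manifest: list[ManifestEntry] = []

    for lib in config.libraries:
        row = abundance[lib]
        source_names = sorted(row)
        probs = np.array([row[s] for s in source_names], dtype=float)
        counts = rng.multinomial(config.reads_per_library, probs)
        lib_reads: list[Read] = []
        serial = 0
        for source_name, count in zip(source_names, counts):
            if count == 0:
                continue
            spec = refs.sources[source_name]
            genome = refs.genome_for(source_name)
            genome_id = f"{source_name}_genome"
            max_start = max(len(genome) - config.read_length, 0)
            for _ in range(count):
                start = int(rng.integers(0, max_start + 1))
                fragment = genome[start : start + config.read_length]
                strand = "+"
                if spec.replicating and config.minus_strand_fraction > 0:
                    if rng.random() < config.minus_strand_fraction:
                        strand = "-"
                seq = revcomp(fragment) if strand == "-" else fragment
                seq = _mutate(seq, config.substitution_error_rate, rng)
                quals = _draw_qualities(
                    len(seq), config.quality_median, config.quality_sd, rng
                )
                read_id = f"{lib}_{serial:06d}"
                serial += 1
                lib_reads.append(Read(read_id, seq, quals, lib))
                manifest.append(
                    ManifestEntry(read_id, lib, source_name, genome_id, strand, start)
                )
        reads[lib] = lib_reads
    return reads, manifest


# ---------------------------------------------------------------------------
# file emission

def write_fastq(reads: list[Read], path) -> None:
    """Sanger FASTQ (Phred+33)."""
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


def write_manifest(manifest: list[ManifestEntry], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tlibrary\ttaxon\tgenome\tstrand\tstart\n")
        for m in manifest:
            fh.write(f"{m.read_id}\t{m.library}\t{m.source}\t{m.genome}\t{m.strand}\t{m.start}\n")


def read_manifest(path) -> list[ManifestEntry]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            read_id, lib, taxon, genome, strand, start = line.rstrip("\n").split("\t")
            out.append(ManifestEntry(read_id, lib, taxon, genome, strand, int(start)))
    return out


def write_references(refs: ReferenceSet, outdir) -> dict[str, str]:
    """Write host/known/novel FASTA + protein DB; returns the path map."""
    from .homology import write_protein_db

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "host": os.path.join(outdir, "host.fasta"),
        "known_viruses": os.path.join(outdir, "known_viruses.fasta"),
        "novel_virus": os.path.join(outdir, "novel_virus.fasta"),
        "protein_db": os.path.join(outdir, "protein_db.fasta"),
    }
    write_fasta([("host_genome", refs.host_genome)], paths["host"])
    write_fasta(
        [(f"{label}_genome", f"species={label}", seq) for label, seq in refs.known_genomes.items()],
        paths["known_viruses"],
    )
    write_fasta([("novel_virus_genome", refs.novel_genome)], paths["novel_virus"])
    write_protein_db(refs.proteins, paths["protein_db"])
    return paths
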
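"""Small nucleotide/protein helpers shared across modules.

Only the standard genetic code is supported; stop codons translate to
``*``. Trailing partial codons are always dropped.
"""

from __future__ import annotations

import numpy as np

CODON_TABLE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = ("TAA", "TAG", "TGA")

#: codons per amino acid, for reverse translation
AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in CODON_TABLE.items():
    AA_TO_CODONS.setdefault(_aa, []).append(_codon)
for _codons in AA_TO_CODONS.values():
    _codons.sort()

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: base -> small int encoding used by the numpy fast paths (N -> 4)
BASE_TO_INT = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
INT_TO_BASE = np.array(list("ACGTN"))


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate a nucleotide string in frame +1, stops as ``*``.

    Trailing partial codons are dropped. ``N``-containing codons
    translate to ``X``.
    """
    aas = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        aas.append(CODON_TABLE.get(codon, "X"))
    return "".join(aas)


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Back-translate an amino-acid string picking synonymous codons at random."""
    return "".join(
        AA_TO_CODONS[aa][rng.integers(len(AA_TO_CODONS[aa]))] for aa in protein
    )


def random_protein(length: int, rng: np.random.Generator, start_met: bool = False) -> str:
    """Random amino-acid string (no stops)."""
    body = "".join(AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), length))
    if start_met and length > 0:
        body = "M" + body[1:]
    return body


def random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


def encode_dna(seq: str) -> np.ndarray:
    """Encode a DNA string as an int8 array (A,C,G,T,N -> 0..4)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, code in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
        out[arr == ord(base)] = code
    return out


def decode_dna(arr: np.ndarray) -> str:
    return "".join(INT_TO_BASE[arr])


def write_fasta(records, path) -> None:
    """Write ``(id, seq)`` or ``(id, description, seq)`` tuples as FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            if len(rec) == 2:
                name, seq = rec
                fh.write(f">{name}\n")
            else:
                name, desc, seq = rec
                fh.write(f">{name} {desc}\n" if desc else f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fasta(path) -> list[tuple[str, str, str]]:
    """Parse FASTA into ``(id, description, sequence)`` tuples."""
    records: list[tuple[str, str, str]] = []
    name, desc, chunks = None, "", []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    records.append((name, desc, "".join(chunks)))
                header = line[1:].split(None, 1)
                name = header[0]
                desc = header[1] if len(header) > 1 else ""
                chunks = []
            elif line:
                chunks.append(line.strip())
    if name is not None:
        records.append((name, desc, "".join(chunks)))
    return records
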
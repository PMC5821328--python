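# virowinnow

A desk-scale, fully tested re-implementation of the winnowing workflow used
to discover novel RNA viruses in multi-library insect metaviromes: host
subtraction, six-frame translated homology binning, greedy
overlap-layout-consensus assembly, known-virus matching, cross-library
expression prioritization, dicistrovirus genome annotation, and
neighbor-joining RdRp phylogenetics with bootstrap support.

Because the original sequencing data are not required, the package ships a
first-class synthetic-data module that emulates the statistical structure of
a four-library metavirome (host reads, known viruses at library-varying
abundance, one planted replicating dicistrovirus, phage/phiX internal
controls, and plant/fungal/bacterial decoys) together with a ground-truth
manifest, so the whole pipeline is exercised end to end with verifiable
expectations.

## Modules

| module | role |
| --- | --- |
| `virowinnow.simdata` | synthetic four-library read sets + references + truth manifest |
| `virowinnow.readfilter` | quality filter (median Phred >= 20, length >= 25) and k-mer host subtraction |
| `virowinnow.homology` | seeded six-frame translated search, Karlin-Altschul E-values, taxonomic binning, phiX removal |
| `virowinnow.assembly` | greedy OLC assembly with per-library singleton bookkeeping |
| `virowinnow.winnow` | known-virus matching (>= 95% nt identity), exclusion rules, library-representation classification and ranking, exact fraction reports; packaged printed-table fixtures |
| `virowinnow.annotate` | ORF calling, dicistrovirus architecture classification, motif-based domain localization, polyA detection, replicative-strand accounting, GFF3 output |
| `virowinnow.phylo` | p/Poisson distances (pairwise deletion), neighbor joining, seeded bootstrap, Newick output |
| `virowinnow.cli` | stage orchestration, YAML config, conservation tallies, reports |

## CLI

```sh
# full pipeline on simulated data
virowinnow all --seed 11 --out runs/demo

# or stage by stage
virowinnow simulate --seed 11 --reads-per-library 2000 --out runs/sim
virowinnow filter --fastq SAL_1=runs/sim/SAL_1.fastq ... --host runs/sim/references/host.fasta --out runs/filtered
virowinnow classify --fasta runs/filtered/non_host.fasta --db runs/sim/references/protein_db.fasta --out runs/binned
virowinnow assemble --fasta virus_reads.fasta --out runs/asm
virowinnow winnow --contigs runs/asm/contigs.fasta --membership runs/asm/membership.tsv \
    --known runs/sim/references/known_viruses.fasta --db runs/sim/references/protein_db.fasta \
    --out runs/winnowed
virowinnow annotate --fasta runs/sim/references/novel_virus.fasta --out runs/ann
virowinnow phylo --alignment alignment.fasta --bootstrap 500 --out tree.nwk

# printed-table fixture arithmetic and run reports
virowinnow fixtures
virowinnow report --run-dir runs/demo
```

`virowinnow all` accepts a YAML config (`--config`) with strict key
checking; see `virowinnow.cli.PipelineConfig` for the schema. Every run
writes a `run_summary.json` whose conservation section asserts the exact
partition invariants (quality filter, host subtraction, binning, assembly,
known-virus matching, exclusions).

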
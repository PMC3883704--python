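# repquant

Repeat-subfamily RNA-seq enrichment analysis: a two-pass quantification of
repetitive-element expression from short single-end reads, followed by
TMM-normalized negative-binomial GLM differential testing with Storey
q-values — plus a synthetic-data generator so the whole pipeline is
testable end-to-end without any external downloads.

## What it does

1. **Quantification** (`repquant quantify`): reads are aligned exhaustively
   against the genome (Hamming distance ≤ v, both strands, complete
   enumeration of hits). Uniquely mapping reads are counted into repeat
   subfamilies by interval overlap with the annotation (≥1 bp; ties go to
   the larger overlap, then the lexicographically smaller subfamily name).
   Multi-mapping reads are aligned against per-subfamily *pseudo-genomes*
   (all genomic instances of a subfamily concatenated with N spacers) and
   contribute 1/k to each of the k distinct subfamilies they hit. The two
   passes are summed per subfamily; the matrix is rounded half-up to
   integers once, at the end. Library size = unique + multi mapping reads.
   A per-sample read-accounting ledger (unique-overlap + unique-other +
   multi-assigned + multi-unassigned + unmapped = total) is enforced
   before any output is written.
2. **Differential testing** (`repquant diff`): TMM scaling factors from
   supplied library sizes, log2 CPM (prior count 0.5), a common NB
   dispersion by Cox–Reid adjusted profile likelihood, per-subfamily NB
   log-linear fits with group-means parameterization, likelihood-ratio
   tests for pairwise group contrasts, and Storey q-values with fixed
   λ = 0.5. All statistics are implemented from the published formulas
   (validated against independent oracles in the test suite), not
   delegated to a stats package.
3. **Simulation** (`repquant simulate`): a toy genome with planted repeat
   subfamilies (per-instance divergence, optional near-identical sibling
   subfamilies to create genuine multi-mappers), replicate FASTQ read sets
   with gamma-Poisson (negative-binomial) count noise across replicates,
   group-specific expression weights (e.g. derepression only in the oldest
   group), and full ground-truth tables.

## CLI

```sh
# simulate a study (omit --spec for the bundled 3 groups × 3 replicates toy)
repquant simulate --spec spec.yaml --out sim/

# quantify FASTQ (or SAM) samples listed in a manifest
repquant quantify --config config.yaml --out quant/

# differential enrichment between groups
repquant diff --counts quant/counts_rounded.tsv --design design.tsv \
    --contrasts old:young,old:mid --out diff/
```

`config.yaml` for `quantify`:

```yaml
genome_fasta: sim/genome.fasta   # FASTA
annotation: sim/repeats.bed      # BED6 or RepeatMasker .out
manifest: sim/manifest.tsv       # columns: sample, group, replicate, fastq
max_mismatches: 2                # Hamming budget v
best_stratum: true               # unique = single best-mismatch-stratum hit
spacer_length: null              # N spacer in pseudo-genomes (default: read length)
reverse_complement_minus: false  # orientation toggle for minus-strand instances
flank: 0                         # genomic flank around instances
seed: 0
```

Outputs are plain TSV/JSON with provenance headers (version, config hash,
seed): `counts_fractional.tsv`, `counts_rounded.tsv`, `accounting.json`,
per-contrast `results_*.tsv` and scatter plots of group-mean log2 CPM with
point size by FDR bin.

## Layout

- `repquant.repeat_annotation_io` — genome/annotation domain types;
  RepeatMasker `.out`, BED6, FASTA, FASTQ I/O (0-based half-open
  coordinates internally).
- `repquant.synthetic_data` — simulation specs, genome/annotation builder,
  per-sample read simulator, study driver, ground-truth tables.
- `repquant.alignment` — exhaustive seeded Hamming aligner,
  unique/multi/unmapped classifier, SAM ingestion/export, library size.
- `repquant.repenrich_core` — pseudo-genomes, unique-overlap counting,
  fractional 1/k assignment, count aggregation and rounding.
- `repquant.differential` — TMM, log2 CPM, common NB dispersion, NB GLM
  likelihood-ratio contrasts, Storey q-values, scatter plots.
- `repquant.pipeline_cli` — configuration, orchestration and the three
  subcommands.
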
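# hostclean

Subtractive host-read decontamination for short- and long-read microbial
FASTQ data. Reads are aligned against a host reference index; any read
with a high-quality host alignment is removed, and for paired data its
mate is removed with it. Output is gzip-compressed FASTQ (optionally with
read names replaced by incrementing integers) plus a conservation-checked
JSON report.

Features:

- **`clean`** — the decontamination pipeline: stream alignment records
  from minimap2 (`sr` preset for short reads, `map-ont` for long reads,
  minimum chaining score 40 enforced for both), decide keep/remove per
  read with pair-aware semantics, and write compressed FASTQ without any
  uncompressed intermediate files.
- **`mask`** — build a microbe-masked host reference: find host regions
  locally similar to a panel of microbe genomes (minimap2 genome-to-genome
  alignment, or a binary-free exact-substring fallback), hard-mask them
  with N, and write the intervals as BED.
- **`index`** — build aligner indexes under deterministic names with
  checksum-based staleness detection.
- **`simulate`** — seeded synthetic fixtures: random genomes,
  Illumina-like read pairs, nanopore-like long reads, and labelled
  host/microbe contamination mixtures.
- **`evaluate`** — truth-based retention/removal metrics with the
  sum-before-divide aggregation rule, run comparison (fold changes with
  bootstrap CIs), and viral-subtraction adjustment of retention figures.

## Usage

```sh
# build an index and decontaminate paired reads
hostclean index host.fa --backend short --name host
hostclean clean --fastq1 r_1.fastq.gz --fastq2 r_2.fastq.gz \
    --index host.short.mmi --aligner short --rename --out-dir out/ --threads 4

# long reads
hostclean clean --fastq1 ont.fastq.gz --index host.long.mmi --aligner long

# mask a host reference against microbe genomes, then re-index
hostclean mask host.fa microbe1.fa microbe2.fa --out-dir masked/
hostclean index masked/host.masked.fa --backend short --name host-masked

# synthetic benchmark
hostclean simulate genome --out g.fa --length 100000 --gc 0.5 --seed 1
hostclean simulate illumina --genome g.fa --n-pairs 1000 --seed 2 \
    --out1 r_1.fq.gz --out2 r_2.fq.gz
hostclean evaluate out/r_1.clean_1.fastq.gz out/r_2.clean_2.fastq.gz \
    --truth truth.tsv
```

`hostclean clean` writes the JSON report to stdout (or `--out FILE`); the
report always satisfies `reads_in == reads_out + reads_removed` and the
run aborts with a distinct exit code if it would not (2 usage, 3
environment, 4 format, 5 conservation, 6 aligner failure).

A pre-computed SAM file can replace the aligner invocation with
`--offline-sam FILE`, which makes the filter engine fully testable without
external binaries.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (conservation
fuzzing, oracle equivalence against a brute-force SAM set-difference,
scaled-down retention benchmarks with the real aligner, masking accuracy,
pair rescue, viral subtraction, simulator calibration, idempotence).

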
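# iaspls

Iteratively Adaptive Sparse Partial Least Squares (IASPLS) classification
of short (60–400 nt) prokaryotic DNA sequences as protein-coding vs.
non-coding.

The package provides:

* **`iaspls.seqio`** — FASTA / label-file IO, sequence validation
  (ambiguity cap), and the four default length classes
  `[60,100) [100,200) [200,300) [300,400]`.
* **`iaspls.features`** — a fixed-order DNA feature catalogue: 252
  Z-curve components (phase-independent + per codon phase, k = 1..3),
  84 k-mer frequencies, GC content, Fop and CAI codon-usage indices,
  third-codon-position base composition, translated-peptide
  hydropathy/aromaticity, 16 dinucleotide odds ratios, and a 65-column
  dinucleotide property profile — 426 columns with the default tables.
* **`iaspls.core`** — the numerical engine: column standardization,
  ridge-regression variable importances, adaptive soft-thresholded
  sparse PLS components (`omega_i = 1/|beta_i|` penalties), iterative
  re-weighting, prediction, JSON model serialization.
* **`iaspls.ensemble`** — odd-K majority-voting training on disjoint
  stratified sub-blocks, and a repeated stratified k-fold
  cross-validation harness with TSV reports.
* **`iaspls.metrics`** — confusion counts and Sn / Sp / ACC / MCC.
* **`iaspls.synthetic`** — seeded generators for sparse linear
  classification data and for coding-like vs. noncoding-like sequences
  (biased codon usage, ATG start, in-frame stop exclusion).

## Command-line usage

The console script `iaspls` exposes five subcommands
(`simulate`, `extract`, `train`, `predict`, `evaluate`). A complete
round trip on synthetic data:

```sh
iaspls simulate --n-coding 200 --n-noncoding 200 --seed 1 \
    --out-fasta demo.fa --out-labels demo.labels
iaspls extract demo.fa --labels demo.labels --out demo.features.tsv
iaspls train demo.features.tsv demo.labels -k 3 --seed 1 --out demo.model.json
iaspls predict demo.model.json demo.features.tsv --out demo.preds.tsv
iaspls evaluate demo.fa demo.labels --folds 5 --repeats 5 -k 3 \
    --seed 1 --out demo.report.tsv
```

Exit codes: 0 success, 2 usage error, 3 data error, 4 numerical
failure. Every subcommand logs its resolved configuration and seed to
stderr.

## Notes

* Codons are always read in frame 0 from the first base; windows with
  ambiguity codes are skipped (never imputed).
* The CAI/Fop reference defaults to the codon counts of the positive
  training sequences (falling back to a shipped E. coli-like usage
  table) and can be overridden with `--codon-reference`.
* All randomness is seed-controlled; identical inputs and seeds give
  bit-identical models, feature tables, and simulated FASTA files.
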
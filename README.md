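# juxtarec

Quantitative toolkit for studying the *heterozygosity juxtaposition*
effect: the local stimulation of meiotic crossovers in heterozygous
chromosome regions that lie next to recombinationally active homozygous
regions.

The package provides:

* **`juxtarec.rf_estimators`** — closed-form recombination-frequency
  (Rf) estimators: fluorescent-seed scoring
  (`Rf = 100(1 − √(1 − 2(g+r)/n))` cM), two-point backcross
  (`Rf = (b+c)/n` with its binomial error), and the coupling-phase F2
  maximum-likelihood estimator (`Rf = 1 − √θ` from the quadratic
  `nθ² − (a−2b−2c−d)θ − 2d = 0`), plus family averaging, sex-balanced
  averaging and Haldane/Kosambi map functions.
* **`juxtarec.meiosis`** — a no-interference (Poisson) meiosis simulator
  over piecewise-constant crossover landscapes, with a
  crossover-redistribution model: heterozygous windows near active
  HOM/HET boundaries are stimulated multiplicatively with exponential
  decay in genetic distance, funded by proportional depletion of
  homozygous donor windows so total map length is conserved.
  `simulate_experiment` runs the five canonical chromosome
  configurations (Inbred, Hybrid, Juxtaposed, Reverse juxtaposed,
  Interrupted juxtaposed) and emits per-plant Rf tables.
* **`juxtarec.het_blocks`** — SNP-density tracks from VCF positions and
  threshold/merge/min-length segmentation into HOM/HET blocks.
* **`juxtarec.boundary`** — boundary-distance analysis: per-individual
  distance from the measurement interval to the nearest homozygous
  boundary, adjacent-homozygous-block length, distance-binned Spearman
  correlation of group mean Rf, and polynomial trend fitting.
* **`juxtarec.stats_compare`** — two-sided Welch t-test, Welch one-way
  ANOVA and the Games–Howell post hoc test (studentized-range based),
  with a seeded permutation fallback for zero-variance groups.
* **`juxtarec.pipeline` / `juxtarec.cli`** — config-driven runs
  (simulate → estimate → compare → boundary analysis) with derived,
  recorded seeds and bit-for-bit reproducible outputs.

## CLI

```sh
# full pipeline from a scenario config
juxtarec run --config examples/scenario.yaml --out runs/demo

# estimate Rf for a segregation-count table
juxtarec estimate --counts counts.tsv --out rf.tsv

# call HET/HOM blocks from a VCF
juxtarec blocks --vcf snps.vcf --chrom chr9 --chrom-length 160000000 \
    --density-out density.tsv --segments-out segments.bed

# boundary-distance grouping + Spearman + cubic trend
juxtarec boundaries --segments segments.tsv --rf rf.tsv \
    --interval 45000000 55000000 --out runs/boundaries

# Welch ANOVA + Games-Howell over a long-format table
juxtarec compare --table long.tsv --out comparisons.tsv
```

Count tables are TSV with columns
`sample_id, cross_id, design{seed|bc|f2}, a, b, c, d, g, r, n, sex`;
segment tables are BED-like TSV (`chrom/sample_id, start, end, state`).
All coordinates are 0-based half-open; VCF positions are converted on
read.

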
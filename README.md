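# sigres

Joint molecular/phenotypic drug-response analysis for landmark-gene
screening designs:

- **io_core** — GCT 1.3 expression matrices, count-table CSVs, drug
  annotations, and assembly of replicate plates into per-(cell line, time
  point) batches with same-plate vehicle controls.
- **chdir** — characteristic-direction signatures: a shrinkage-regularized
  discriminant direction per treated replicate vs. same-plate controls,
  batch-averaged into a unit condition signature whose pre-normalization
  magnitude is the effect amplitude.
- **scs** — signature consistency scoring: mean pairwise cosine distance of
  replicate directions, compared against an empirical null built by drawing
  matched replicate sets from the batch pool (plate-stratified); the score
  is −log10 of the lower-tail empirical p, so score > 1.3 ⇔ p < 0.05.
- **clustering** — consensus fuzzy c-means (fuzzifier 1.22, 101 runs,
  55 % membership cutoff) on unit signatures, consensus signatures,
  percentile-thresholded signature networks, and binomial cluster-category
  enrichment.
- **gr_metrics** — growth-rate inhibition values from viable-cell counts
  (GR = 1: untreated growth; 0: cytostasis; < 0: cytotoxicity), GR_AOC
  summaries and sigmoidal (GR_inf, GEC50, hill) fits with a flat-line
  fallback.
- **response_classes** — quadrant classes I–IV from paired GR (cutoff 0.66)
  and consistency score (cutoff 1.3).
- **synergy** — excess over Bliss independence on the GR scale for
  checkerboard dose grids, with replicate-level t-tests.
- **variability** — cross-cell-line CV/SD statistics by drug class,
  dose-shift cosine geometry, cross-line variability of log abundance
  tables, Spearman correlation.
- **synthetic_data** — seed-deterministic generator of expression batches,
  count tables and combination checkerboards with planted ground truth
  (shared vs. cell-line-specific response directions, dose-dependent
  amplitude, sigmoidal GR curves, planted synergy), used by the test suite
  as a recovery oracle.

## Tests

```sh
python -m pytest -q
```

`tests/test_acceptance.py` holds the acceptance criteria (GR formula
semantics, score scale, null calibration, discriminant oracles, Bliss
identity, planted-structure recovery, GR parameter recovery, network
percentile contract).

## CLI

```sh
sigres simulate --seed 0 --out-dir data/            # GCT + CSV + ground truth
sigres signatures data/expression.gct --seed 0      # directions + scores
sigres cluster signatures_vectors.tsv --k 20        # consensus clusters + network
sigres gr data/counts.csv                           # GR values + profiles
sigres classify gr_values.csv signatures_scores.csv # class I–IV table
sigres combo combo_counts.csv                       # excess-over-Bliss grid
```

All subcommands accept `--seed`, `--config` (YAML overriding simulation /
analysis defaults) and `--log-level`.

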
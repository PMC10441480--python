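# protscreen

Property-scale ensemble regression for pre-screening protein variant
libraries.

`protscreen` turns a library of characterized point mutants into a stacked
regression ensemble and uses it to pre-screen an in-silico saturation-
mutagenesis library before anything is cloned. Sequences are encoded with
amino-acid property scales (AAINDEX-style indices); three regressor families
(random forest, K-neighbors, MLP) are tuned per scale, the top five scales
per family are stacked into a mean-of-15 ensemble, and per-variant
predictions are analyzed with t-test volcano statistics, sigma bands, and
residue-prevalence tables. A companion module quantifies fluorescence
time-series traces (dF/F0, SNR, decay constant, half-decay time, dynamic
range, SNR/tau performance score).

## Modules

| module | what it does |
| --- | --- |
| `protscreen.library_io` | parse/validate mutation-list libraries, dedup-average, normalize to a reference, 80/20 split |
| `protscreen.aa_encoding` | AAINDEX-1 flat-file parsing, property / random-label / one-hot encodings |
| `protscreen.ensemble` | per-scale feature selection + grid search, scale ranking, stacked mean-of-15 ensemble |
| `protscreen.saturation` | single-point saturation library generation and redundancy removal |
| `protscreen.analysis` | predicted change vs base, contributor t-tests, sigma bands, prevalence counts |
| `protscreen.clustering` | standardize, PCA at an explained-variance threshold, K-means with the elbow rule |
| `protscreen.traces` | fluorescence trace metrics and exponential decay fitting |
| `protscreen.simulate` | synthetic libraries (additive property effects) and traces for testing |
| `protscreen.cli` | `protscreen` command-line entry points |

A curated 20-entry AAINDEX-format fixture (18 complete scales, 2
deliberately incomplete) ships in `src/protscreen/data/`, so nothing needs
to be downloaded.

## CLI

```bash
# synthetic inputs
protscreen simulate --kind library --n-variants 600 --out runs/sim
protscreen simulate --kind trace --out runs/sim

# sweep property scales and rank them per regressor family
protscreen train --base-fasta runs/sim/base.fasta \
    --library-csv runs/sim/library.csv --target phenotype \
    --seed 42 --out runs/train

# saturation library minus redundancies
protscreen saturate --base-fasta runs/sim/base.fasta \
    --positions 3,7,11,42 --out runs/sat

# stack top-5-per-family and predict the novel library
protscreen predict --base-fasta runs/sim/base.fasta \
    --library-csv runs/sim/library.csv \
    --novel-csv runs/sat/novel_library.csv --target phenotype \
    --train-dir runs/train --seed 42 --out runs/pred

# volcano + prevalence statistics, clustering, trace metrics
protscreen analyze --predictions-csv runs/pred/predictions.csv \
    --novel-csv runs/sat/novel_library.csv \
    --base-fasta runs/sim/base.fasta --out runs/analysis
protscreen cluster --input-csv features.csv --out runs/clusters
protscreen metrics --traces-csv runs/sim/trace.csv --out runs/metrics
```

Defaults follow the source protocol: 80/20 split with seed 42, top 5 scales
per family, 2.5% prediction tails, +/-3 sigma bands, 0.8 explained-variance
threshold, 50-sample baseline window (30 for KCl-style assays). A YAML
config (`--config`) can override any of these, including the hyperparameter
grids.

## Caveats

- Grid points are scored on the same held-out split used for final
  reporting (single-split protocol, no inner CV); sweep R^2 values are
  optimistically biased model-selection scores, not generalization
  estimates.
- The per-variant t-tests compare 15 contributor predictions that are not
  independent samples; their p-values are heuristic ranking scores for
  volcano displays, not calibrated inference. No multiple-testing
  correction is applied.
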
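# weightscape

A toolkit for combined subjective–objective indicator weighting and
grading, built around four chained stages:

1. **Pairwise-comparison priorities with interdependence** (`weightscape.anp`):
   principal-eigenvector priorities of reciprocal judgment matrices,
   consistency index/ratio checking against the standard random-index
   table, criterion re-weighting through a column-stochastic dependency
   matrix, global sub-criterion weights over a two-level hierarchy, and
   optional supermatrix synthesis.
2. **CRITIC objective weighting** (`weightscape.critic`): min–max score
   normalization, contrast intensity (standard deviation), conflict
   (pairwise Pearson correlation), information content, and normalized
   weights from a respondents × indicators score table.
3. **Least-squares fusion** (`weightscape.fusion`): combines the two
   weight vectors by an equality-constrained quadratic program with
   configurable trust coefficients, plus per-criterion share summaries.
4. **Rank-sum-ratio grading** (`weightscape.rsr`): ascending ranks,
   cumulative percentages with the `(1 − 1/(4m))·100%` top-entry
   substitution, probit transform `Φ⁻¹(P) + 5`, and half-open-interval
   grades. A `legacy_percent_table` mode truncates percentages to whole
   percents before the transform, matching results produced from
   classical printed probit lookup tables.

A synthetic Likert-survey generator (`weightscape.synth`) makes the
objective stage testable without real cohort data: correlated latent
traits (Gaussian copula), three 9/7/5/3/1-scored agreement items per
indicator, linear rescaling onto a 0–10 score, and incomplete-response
injection/filtering. `weightscape.fixtures` bundles a published
eleven-indicator social-support case study as an offline verification
fixture.

## CLI

```sh
weightscape fixtures export --out fx/          # write the bundled case study as files
weightscape run --config fx/pipeline.yaml      # full pipeline -> fx/out/report.md

weightscape anp --hierarchy fx/hierarchy.yaml --dependency fx/dependency.csv \
    --supermatrix fx/supermatrix.csv --out anp.json
weightscape synth --config cohort.yaml --seed 1 --out scores.csv
weightscape critic --scores scores.csv --out critic.json [--std-mode sample]
weightscape fuse --subjective anp.json --objective critic.json --out fused.json
weightscape rsr --weights fused.json --mode legacy_percent_table --out rsr.json
```

Matrix CSVs accept exact fractions (`1/3`) as well as decimals. Exit
codes: 2 validation/configuration, 3 computation, 4 degenerate data.

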
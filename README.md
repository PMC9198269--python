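# cellscreen

Drug-sensitivity biomarker screening and ranking for cancer cell-line
cohorts. The package:

- **normalizes** expression cohorts (median-of-ratios size factors →
  quantile normalization → scaling so every cell line's mean expression is
  1000; pre-normalized matrices get the scaling step only), filters
  majority-zero genes and resolves gene symbols via an HGNC-style alias map;
- **classifies** cell lines as sensitive / resistant / excluded per compound
  and dataset from IC50 or AUDRC values (tertile or median scheme);
- **screens** single-gene biomarkers with folded ROC AUC + direction,
  Mann-Whitney p, Spearman rho versus the response values, and
  Benjamini–Hochberg q-values; supports mean-expression multi-gene
  signatures and a filtered Spearman correlation matrix;
- **builds random-forest gene signatures**: stratified 66/34 train/test
  split, Mann-Whitney selection (p < 0.05, training set only), 500-tree
  forest, held-out confusion matrix / accuracy / sensitivity / specificity /
  precision / test ROC AUC;
- **ranks cell-line models** by standardized AUDRC and reports Venn-style
  overlaps of compounds, cell lines and genes across 2–4 datasets;
- **simulates** multi-dataset cohorts (log-normal counts, Hill-curve
  dose-response driven by a latent resistance score, planted biomarker
  genes) so the whole pipeline is testable without any external download.

## Command-line interface

The console script `cellscreen` exposes subcommands
`simulate`, `normalize`, `classify`, `screen`, `signature`, `rank`,
`overlap`, `run-all`. Exit codes: 0 success, 2 validation error, 1 runtime
error. A typical synthetic round trip:

```sh
# spec.yaml mirrors SyntheticCohortSpec field-for-field
cat > spec.yaml <<EOF
n_genes: 100
n_cell_lines: 200
seed: 7
planted_genes: [[0, 2.0, 1]]
EOF

cellscreen simulate --spec spec.yaml --out data/
cellscreen normalize --expr data/expression_DS1.tsv --state raw_counts --out norm.tsv
cellscreen classify --responses data/responses.tsv --dataset DS1 \
    --compound DRUG1 --scheme tertile --out labels.tsv
cellscreen screen --expr data/expression_DS1.tsv --responses data/responses.tsv \
    --dataset DS1 --compound DRUG1 --out stats.tsv
cellscreen rank --responses data/responses.tsv --dataset DS1 --compound DRUG1 \
    --k 10 --out rank.tsv
cellscreen overlap --category cell_lines --responses data/responses.tsv --out venn.json
cellscreen signature --expr data/expression_DS1.tsv --responses data/responses.tsv \
    --dataset DS1 --compound DRUG1 --gmt sets.gmt --set NAME --seed 42 --out sig.json
cellscreen run-all --config config.yaml --out report/
```

Input formats: expression TSV (gene symbols in column 1, cell-line ids as
header), response TSV (`dataset, compound, cell_line, ic50, audrc`; empty
string = missing), Broad-dialect GMT gene sets, and an HGNC-style map TSV
(`approved_symbol, alias_symbols, previous_symbols`, pipe-separated).

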
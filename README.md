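# pathact

Pathway-activity-based discrimination of tumor from normal cells in
single-cell RNA-seq.

Annotating which cells in a cancer scRNA-seq sample are malignant is hard
because droplet data are extremely sparse: most marker genes are simply not
detected in most cells, so marker-based annotation under-calls tumor cells,
and copy-number inference fails on tumors without strong CNV. `pathact`
sidesteps per-gene sparsity by featurizing each cell as a vector of
**gene-pathway activity scores** — for pathway *P* with matched gene set
*P∩G* in a cell *c* with library-normalized, log-transformed expression
*x<sub>gc</sub>*:

    s(P, c) = (1 / |P∩G|) * Σ_{g ∈ P∩G} x_gc        (zeros included)

Pooling dozens of genes per pathway means a cell still gets a graded
activity value when only a handful of the pathway's genes survived dropout;
including the zeros preserves the observation that tumor cells typically
express more detected genes than normal cells. The pipeline is then:

1. **Score** pathways per cell from raw counts (library-size normalization
   to 10,000 counts, log1p, mean over pathway genes).
2. **Select** pathways whose scores separate tumor from normal cells by a
   two-sided Wilcoxon rank-sum test (retain *p* < 0.05).
3. **Classify** cells with a small fully connected network
   (input → 128 → 64 → 1, ReLU/sigmoid, dropout, Adam on binary
   cross-entropy, early stopping), trained on a stratified 8:2 split.
4. **Explain** the classifier by permutation importance: shuffle each
   pathway's standardized score row across cells and measure the increase
   in loss (100 randomizations per pathway).
5. **Stress-test** it by randomly retaining *n* genes per cell or randomly
   inactivating a fraction of pathway features at prediction time.

A negative-binomial synthetic-data generator with planted up/down pathway
effects, a tumor library-size shift and logistic dropout makes every stage
testable without downloads.

## Worked example

A complete run on a generated dataset (600 cells, 2,000 genes, 40 pathways
of which 4 are planted up-regulated and 4 down-regulated in tumor cells at
one log2 unit):

```bash
pathact generate --out data --seed 11 --config sim.json
pathact score    --counts data/counts --gmt data/pathways.gmt --out scored
pathact select   --scores scored/scores.tsv --labels data/labels.tsv \
                 --out selected --differential
pathact train    --scores scored/scores.tsv --labels data/labels.tsv \
                 --selected selected/selected_pathways.tsv --out model --seed 11
pathact predict  --model model/model.json --scores scored/scores.tsv --out pred
pathact importance --model model/model.json --scores scored/scores.tsv \
                 --labels data/labels.tsv --out imp --repeats 100 --seed 11
pathact simulate --model model/model.json --labels data/labels.tsv \
                 --protocol pathways --scores scored/scores.tsv \
                 --levels 0,0.2,0.4,0.6,0.8 --replicates 5 --seed 11 --out sim
```

prints

```
generate: seed=11 cells=600 genes=2000 pathways=40
score: 40 pathways x 600 cells, 0 dropped
select: retained 40 of 40 pathways at p<0.05
train: seed=11 held-out F1=1.0000 accuracy=1.0000
predict: 300 of 600 cells called tumor
importance: top pathways PW0025, PW0040, PW0017, PW0010
simulate: level=0.0 mean_f1=1.0000
simulate: level=0.2 mean_f1=0.9980
simulate: level=0.4 mean_f1=0.9847
simulate: level=0.6 mean_f1=0.9338
simulate: level=0.8 mean_f1=0.8820
```

Reading the output: the held-out fifth of cells is classified perfectly;
the four pathways the permutation-importance table ranks first (PW0025,
PW0040, PW0017, PW0010) are all planted ones; and mean F1 stays at 0.93
even when a random 60% of the pathway features are zeroed at prediction
time — the pathway representation is heavily redundant, which is exactly
why it tolerates sparse input. Every command writes a JSON run manifest
(arguments, seeds, input checksums) next to its outputs.

The same API is available from Python: `pathact.score_counts`,
`pathact.wilcoxon_filter`, `pathact.train_model`,
`pathact.permutation_importance`, `pathact.robustness_curve`,
`pathact.generate_dataset`.

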
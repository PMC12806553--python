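# Methods

## Pathway activity scores

Raw counts are library-size normalized per cell to `target_sum` (default
10,000) and log1p-transformed; the activity of pathway *P* in cell *c* is
the mean normalized value over the pathway genes present in the matrix,
with undetected genes contributing zeros. Two conventions matter:

* **Zeros are included** in the mean. Detection itself is informative —
  tumor cells express more detected genes than normal cells — and a
  detected-genes-only mean would discard that signal.
* **Genes in a pathway but absent from the matrix are ignored**, not
  treated as zeros: their absence says something about the platform's gene
  universe, not about the cell. The number of matched genes is recorded per
  pathway (`n_genes_used`), and pathways matching fewer than `min_genes`
  (default 3; a mean over fewer genes no longer pools dropout) are dropped
  and reported.

The mean-expression score is deliberately the simplest formula with the
pooling property; it is isolated in a single function
(`pathway_scoring.score_pathways`) so a rank-based or background-corrected
variant could be swapped in without touching anything downstream. Gene
symbols are uppercased and stripped before matching — symbol-case mismatch
is the most common silent join failure between expression matrices and GMT
files — and duplicate gene rows are summed on read so pathway membership
stays well-defined.

## Pathway selection and differential reporting

Two operations share the same two-sided Wilcoxon rank-sum machinery but are
intentionally separate because they act at different pipeline stages:

* the **training-time filter** retains pathways with raw *p* < 0.05, no
  multiplicity correction — a deliberately permissive screen whose job is
  only to discard uninformative features before the network sees them;
* the **differential table** reports log2 fold change
  log2((m̄_tumor + ε)/(m̄_normal + ε)) with ε = 0.01 guarding unexpressed
  pathways, and flags |log2FC| > 1 with Benjamini–Hochberg FDR < 0.05.

For group sizes up to 8 with no ties the p-value is computed by exact
enumeration; otherwise the normal approximation with tie and continuity
correction is used. A pathway whose scores are identical across all cells
gets *p* = 1 by convention. The test pools all cells into one
tumor-vs-normal comparison rather than testing per dataset.

## Classifier

A fully connected network maps the selected-pathway score vector to a tumor
probability: input → 128 (ReLU) → dropout 0.3 → 64 (ReLU) → dropout →
1 (sigmoid). Training minimizes binary cross-entropy with Adam
(learning rate 1e-3, batch 256, at most 200 epochs), early-stopped on a
stratified internal 10% validation fold with patience 10 and best weights
restored. The feature space after selection is a few hundred pathways at
most, so this small network implemented directly on numpy trains in seconds
and — with all randomness drawn from one seeded generator — is
bit-reproducible: the same data and seed give identical weights, and a
saved model reloaded from its JSON artifact reproduces predictions exactly.
Loss values used for early stopping and for importance are computed from
logits via the stable softplus form, which has no clipping floor.

Per-pathway standardization (mean 0, population SD 1 on the training cells;
zero-variance pathways get scale 1 so they map to constant 0) is fitted on
the training split only and embedded in the model artifact together with
the ordered pathway list, the normalization parameters, the decision
threshold (default 0.5, ties called tumor) and the training configuration,
so prediction from raw counts is fully reproducible from the single file.
Prediction realigns incoming score matrices by pathway name and refuses to
run if a model pathway is missing.

Metrics treat tumor as the positive class; when a denominator is zero,
precision/recall/F1 report 0 rather than being undefined, so a degenerate
all-negative predictor is penalized, not hidden.

## Permutation importance

The importance of pathway *p* is the mean increase over the baseline in
mean binary cross-entropy when *p*'s standardized score row is shuffled
across cells, everything else fixed, repeated `n_repeats` (default 100)
times with a fresh permutation per repeat. Shuffling happens post-scaler so
the scaler is not refit — the standard permutation-importance contract that
isolates how the *model* uses the feature. Each (pathway, repeat) draw is
seeded from (seed, pathway index, repeat), making tables reproducible and
independent of evaluation order; ranks break ties lexicographically by
pathway name. Importance is evaluated on held-out cells by default.

Known limitation: permutation importance divides credit among correlated
features. When many pathways carry redundant class signal — as happens
whenever a global library-size difference between classes shifts every
pathway score — single-feature shuffles barely move a confident model's
loss, and the ranking among moderately-important features becomes noisy.
The paired ablation experiment (retrain on top-k only vs all-but-top-k) is
the sharper instrument in that regime and is provided alongside.

## Degradation protocols

* **Gene retention**: per cell, a uniform random subset of its detected
  genes of size min(n, detected) keeps its counts; everything else is
  zeroed. Scores are recomputed from the degraded counts with the model's
  embedded normalization, so the curve reflects the full pipeline's
  response to shallower detection. Retention is per cell because the number
  of detected genes is a per-cell property.
* **Pathway inactivation**: a uniform random ⌊f·P⌋ of the standardized
  score rows are set to 0 — the training mean — at prediction time. Zeroing
  rather than shuffling is the operator because inactivation should remove
  the feature's information; a shuffle would preserve its marginal
  distribution. The operator is isolated so a different choice can be
  substituted.

Default levels: 100/200/500/1000/2000/5000 retained genes, inactivated
fractions 0/0.2/0.4/0.6/0.8, 10 replicates per level, mean ± SD of F1
reported per level.

## Synthetic data generator

Counts for gene *g* in cell *c* are negative binomial with size
(dispersion) *r* and mean μ<sub>gc</sub> = baseline<sub>g</sub> ·
effect<sub>gc</sub> · lib<sub>c</sub>, followed by dropout that zeroes an
entry with probability sigmoid(−slope · (log μ<sub>gc</sub> − midpoint)).

* baseline<sub>g</sub> ~ lognormal(μ = −0.7, σ = 1.0): a realistic skewed
  mean-expression profile averaging ~0.5 counts/gene at unit library.
* effect: genes are partitioned into non-overlapping pathways (sizes
  uniform in `genes_per_pathway`; leftover genes belong to no pathway);
  planted "up" pathways have tumor means multiplied by 2^effect_log2fc,
  "down" pathways by 2^−effect_log2fc. Non-overlapping by default so
  planted-truth recovery is unambiguous (real KEGG pathways overlap
  heavily; an overlap option is out of scope).
* lib<sub>c</sub> = `tumor_library_scale` (default 1.5) for tumor cells:
  tumor cells get more counts and — because dropout falls with the mean —
  more detected genes, reproducing the detection-count asymmetry seen in
  real tumor scRNA-seq.
* dropout midpoint 0.0 and slope 1.0 give ~80–85% zeros at the default
  configuration, typical of droplet data.

Everything is drawn from a single seeded generator, so a config and seed
fully determine the dataset.

What the generator does **not** emulate: batch effects, doublets, ambient
RNA, cell-type substructure within the normal compartment, CNV profiles,
and gene–gene correlation beyond pathway-level mean shifts. Passing tests
on this generator therefore demonstrate that the pipeline recovers planted
pathway-level signal under NB noise and heavy dropout — not that it
matches real-data marginals.

One consequence worth stating explicitly: with a tumor library-size shift
active, *every* pathway's zero-included mean score separates the classes at
large n, not just the planted ones, so the rank-sum filter legitimately
retains essentially all pathways on such data. Null calibration of the
filter is therefore checked under a true global null (effect 0, equal
library scale), where the retained fraction at α = 0.05 sits inside the
binomial envelope.

## Frozen benchmark

The benchmark configuration used by `scripts/acceptance.py` and the
end-to-end tests: 1,000 tumor + 1,000 normal cells, 5,000 genes, 100
pathways of 25–60 genes, 10 up + 10 down planted at effect_log2fc 1.0,
dispersion 0.5, tumor library scale 1.5, stratified 8:2 split. These sizes
run the complete pipeline in seconds on one CPU while leaving enough cells
(400 held out) for stable metric estimates. On this benchmark the
classifier reaches held-out accuracy ≥ 0.95 and keeps mean F1 ≥ 0.8 under
random 60% pathway inactivation — both quantities are recomputed from
scratch, never stored.

## Numerical conventions

* Stratified splits preserve class proportions to within one cell and are
  deterministic given the seed.
* Model artifacts are versioned JSON with weights as explicit arrays;
  floats round-trip exactly (shortest-repr serialization).
* Probability exactly at threshold → call tumor (≥ convention).
* BH adjustment is the standard step-up with monotonicity enforcement,
  order-preserving.
* TSV outputs are written at full float precision (`%.17g`).
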
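# Methods

## Problem setting

Given a protein sequence, every lysine is a candidate SUMOylation site. A
candidate is represented by a fixed odd-length peptide window (default
L = 39) centered on the lysine; positions that fall outside the protein are
padded with the placeholder `X`. Windows are scored by a binary classifier;
scores in [0, 1] are interpreted as modification probabilities. Coordinates
are 1-based throughout.

## Feature encodings

All amino-acid-indexed channels use the fixed order `ACDEFGHIKLMNPQRSTVWY`,
recorded in every serialized artifact so trained weights are portable.

- **EAAC** — a length-w sub-window (default w = 5, step 1) slides from the
  N- to the C-terminus; each row holds the 20 amino-acid frequencies within
  the sub-window, with denominator fixed at w. `X` counts toward no channel,
  so rows covering padding sum to less than one rather than being
  renormalized; this keeps terminal windows distinguishable from internal
  ones. Shape (L−w+1)×20.
- **BLOSUM62** — each residue contributes its row of the standard NCBI
  BLOSUM62 matrix (loaded from biopython). `X` contributes a zero row; the
  matrix's own X column is deliberately ignored so the padding convention is
  identical across encoders. Shape L×20.
- **AAindex** — each residue contributes the values of the selected
  physicochemical property scales, raw by default (a `standardize` switch
  z-scores each scale over the 20 amino acids). `X` → zero row. The package
  ships a curated table of 16 classical published scales
  (`data/aaindex_like.tsv`: Kyte–Doolittle, Hopp–Woods, Eisenberg,
  Fauchère–Pliska, Grantham polarity and volume, Chou–Fasman helix/sheet/turn,
  Zimmerman bulkiness and pI, residue mass, Vihinen flexibility, Janin
  transfer energy, Charton polarizability, Jones refractivity); any
  user-supplied table in the same TSV layout can be loaded instead, so the
  full AAindex database can be dropped in where it is available. Shape
  L×n_selected.
- **ZScale** — the five Sandberg descriptors per residue (z1 lipophilicity,
  z2 steric bulk, z3 polarity, z4/z5 electronic character); `X` → five
  zeros. Shape L×5.

**Property selection.** `rank_and_select_aaindex` scores each property alone
by stratified five-fold random-forest AUC, ranks properties by AUC
(descending, ties broken by property id), re-scores each top-k prefix over a
k grid (default every integer 1..min(64, n)), and keeps the smallest k
attaining the maximal AUC. Selection depends on the property table supplied;
counts quoted for specific AAindex database versions are not asserted
anywhere.

## Classifiers

- **Random forest** — 140 trees (scikit-learn), seeded, on flattened
  encodings.
- **LightGBM** — defaults num_leaves 31, learning rate 0.1, 200 trees; an
  optional 3-fold grid search over num_leaves {15, 31, 63} × learning rate
  {0.05, 0.1} × n_estimators {100, 200, 400} (AUC-scored) can be switched on
  in the config.
- **Plain CNN (CNN-n)** — n blocks of [conv(128 kernels, size 3, "same") →
  batch-norm → ReLU → max-pool(pool 2, stride 1, "same") → dropout 0.5],
  then flatten → dense 128 → dense 64 (both ReLU, L2 penalty 0.01) → single
  sigmoid unit. Same-padding and stride-1 pooling keep the position count at
  L through any depth.
- **Residual CNN** — one plain convolution block followed by two residual
  module blocks and the same dense head; five convolution sublayers in
  total. A residual block computes `x_t = P(R(x_{t−1} + δ(x_{t−1}, w_t)))`
  with δ = conv → BN → ReLU → conv → BN (the standard pre-pool ordering; the
  internal activation placement is a design choice of this package) and an
  identity skip, which requires equal input/output channel counts.

The networks run on a purpose-built seeded numpy engine (`sumosite.nn`):
1-D convolution via shifted matrix products, batch normalization with
moving-average inference statistics (momentum 0.99, eps 1e-3), inverted
dropout, He/Glorot-style initialization, Adam (lr 1e-3, β 0.9/0.999), and a
numerically fused sigmoid/binary-cross-entropy loss. All tensors are
float32; weight initialization and dropout masks draw from a single
generator derived from the model seed, so single-threaded runs are
bit-reproducible. Dropout sits after the pooling step of each plain
convolution block and is not applied inside residual blocks.

**Training contract.** Adam on binary cross-entropy; defaults batch 512, at
most 500 epochs, early stopping once validation accuracy (threshold 0.5) has
not improved for 50 epochs, restoring the best-validation state. Every epoch
is logged (train/validation loss and accuracy) and can be exported as CSV.
Inside cross-validation the held-out fold doubles as the early-stopping
validation set; this mildly optimistic convention matches the reference
protocol and is noted here as a caveat — an inner validation split can be
passed explicitly instead via `train_network`.

## Evaluation protocol

From the confusion matrix at a threshold: Sn = TP/(TP+FN), Sp = TN/(TN+FP),
ACC = (TP+TN)/N, MCC = (TP·TN − FP·FN)/√((TP+FN)(TN+FP)(TP+FP)(TN+FN)).
Metrics with vanishing denominators are returned as NaN after an explicit
warning. AUC is the tie-aware Mann–Whitney statistic
P(s⁺ > s⁻) + ½P(s⁺ = s⁻), computed from average ranks; the test suite pins
it to a brute-force pair-counting oracle to 1e−12.

**Fixed-specificity comparison.** Each model's decision threshold is the
linear-interpolation empirical 0.650-quantile of its *negative* scores;
windows scoring strictly above it are called positive. On tie-free scores
the achieved specificity lies within 1/n_neg of the target; heavily tied
scores (e.g. vote proportions from small tree ensembles) quantize the
achievable specificities and are flagged with a warning rather than silently
reported. On balanced data ACC = (Sn + Sp)/2 exactly.

**Cross-validation.** Stratified k-fold (default 5): per class, shuffled
indices are dealt round-robin, so class counts per fold differ by at most
one. Results are reported per fold and as mean ± sample (n−1) standard
deviation. The 9:1 CV/independent split uses a per-class floor rule —
floor(0.9 · n_class) items to CV — so 37,273 items per class yield exactly
33,545 CV and 3,728 independent items. Splitting is by site, not by parent
protein; homologous sites can therefore co-occur across partitions (the
upstream 40%-identity clustering is what limits this).

**Sweeps** rerun the full cross-validation per setting with one master seed,
so settings differ only in the swept variable; the window-length axis re-cuts
windows to the shorter length (trimming a centered window is identical to
re-extraction) and re-encodes. **Model comparison** uses a classical paired
two-sided t-test on fold-wise metrics; zero-variance differences return
p = 1.0 when the mean difference is zero and are flagged as degenerate
otherwise.

## Two-sample logo

For each non-central position and each of the 20 residues, occurrence
indicators in the modified vs unmodified sets are compared with a Welch
t-test (asymptotically the two-proportion z-test; the indicator-t form is
used as it is the convention for this analysis) and Bonferroni-corrected by
(L−1)×20. `X` padding is excluded from the per-position denominators.
Output is tabular; drawing a logo image is left to plotting glue.

## Benchmark construction

Pipeline order: greedy clustering at 40% identity → one representative per
cluster (most SUMOylation sites; ties: longer sequence, then id) → positives
= representatives' annotated sites → candidate negatives = their remaining
lysines → drop candidates with any PTM annotation → sample negatives
uniformly without replacement (global, not per-protein) to match the
positive count → window extraction → 9:1 split → fold assignment. Stage
counts are logged and returned.

Clustering is a self-contained simplification of CD-HIT: sequences are
processed in decreasing length order; each joins the first cluster whose
founding sequence it matches at ≥ threshold identity, where identity =
aligned match count / shorter sequence length (global alignment, match 1 /
mismatch 0 / gap −1, −0.5 extension; a shared-3-mer prefilter short-circuits
obvious non-matches). This reproduces the pipeline's structure at desk
scale; it does not reproduce CD-HIT's exact cluster counts on real
proteomes, and no such counts are asserted.

## Synthetic data

`MotifModel` plants the consensus motif ΨKX[ED] (Ψ drawn uniformly from
{V, I, L, M, F}, the X slot left as background, the acidic slot uniform over
{E, D}) with probability `p_consensus` and the inverted motif [ED]XKΨ with
probability `p_inverted` in each positive window; negatives are pure
background with the central lysine forced. The defaults are
p_consensus = p_inverted = 0.5 over a uniform background: every positive
then carries one of the two motif contexts, mirroring the observation that
identified sites predominantly conform to one of them, and making the
planted signal strong enough that classifier-recovery experiments measure
optimization behaviour rather than Bayes-limit noise. (With only the
consensus motif at probability 0.5 and nothing else, half the positives
would be distributionally identical to negatives and no classifier could
exceed AUC ≈ 0.74 under a uniform background — a useful null to keep in
mind when configuring custom simulations.) A human-proteome-like background
composition is shipped as an option.

What the generator deliberately does **not** emulate: positional preferences
beyond the four motif slots, correlations between positions, homology
between windows, class imbalance, or the weak/partial motif matches of real
proteomes. Tests passing on this generator therefore demonstrate that the
machinery (encodings, optimization, evaluation, statistics) behaves
correctly — not that any particular real-data AUC will be attained.

## Desk-scale experiment sizes

The end-to-end experiments (acceptance script and end-to-end tests) use
2,000 peptides per class, ZScale encoding, five folds, and a training
schedule of batch 128 with at most 4 epochs. The batch size is scaled down
with the dataset so the optimizer takes a comparable number of steps per
epoch as the full-scale contract (512 × ~100 steps on a ~53k-window
benchmark vs 128 × 25 steps here); on the strongly separable planted-motif
task the networks converge within these budgets. The library defaults
(batch 512, 500 epochs, patience 50) remain the full-scale contract.

At these sizes the depth-degradation effect is pronounced: an 8-layer plain
CNN trains much more slowly than a 2-layer one (batch-norm statistics and
gradient flow through eight stride-1 pool/conv stages), while the
five-conv-layer residual network matches or exceeds the shallow CNN —
qualitatively the same ordering reported for the full-scale benchmark.

## Numerical choices and degenerate inputs

- Decision rule is strictly "score > threshold"; the quantile uses numpy's
  linear interpolation.
- MCC's standard numerator TP·TN − FP·FN is used.
- Ranks for AUC come from `scipy.stats.rankdata` (average ranks for ties).
- Non-standard residues (B, J, O, U, Z, *) map to `X` with a logged warning
  rather than erroring, since the padding symbol already flows through every
  encoder; duplicate FASTA ids error by default (opt-in suffixing).
- Duplicate windows are kept (an opt-in flag deduplicates).
- Empty classes, single-class inputs, even window lengths, k > n folds,
  zero backgrounds and unfitted models all raise explicit errors.

## Known limitations

- The numpy engine is single-threaded and CPU-bound; it is sized for
  desk-scale experiments (thousands of windows), not proteome-scale training.
- Early stopping on the held-out fold is mildly optimistic (see above).
- The clustering identity measure is simpler than CD-HIT's banded
  short-word heuristics; cluster boundaries can differ on borderline pairs.
- The shipped property table is a 16-scale curated subset; the AUC-ranked
  selection procedure is exercised and tested on it, but enrichment of the
  full 500+-scale database requires supplying that table.
- No GPU support and no hyperparameter search beyond the documented grids.
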
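# Methods

## The problem

During the maternal-to-zygotic transition, the embryo switches from
maternally deposited transcripts to transcription from its own genome
(zygotic genome activation, ZGA).  The timing differs by species — mouse at
the 2-cell stage, human and pig at 4–8 cells, bovine and goat at 8–16 cells
— and the genes activated then ("ZGA genes") carry distinctive regulatory
signals: short sequence words enriched in their TSS/TES flanks and an
active chromatin state (H3K9ac, H3K4me3, Pol II) around the TSS.  `zgakit`
implements the desk-scale analysis chain for this problem: call ZGA genes
from staged expression tables, learn sequence and chromatin classifiers
that separate them from silent genes, interpret the classifiers with
Shapley attribution, relate salient words to known TF motifs, and screen
genome-wide score tables with a combined high-confidence rule.

## ZGA calling (expression module)

A gene is called ZGA when any ratio condition of the species ruleset
fires.  Each preset carries five conditions; for mouse:
early2C/1C > 2.5, late2C/1C > 3, early2C/MII > 3, late2C/MII > 3,
late2C/early2C > 3 (human/pig and bovine/goat analogues shift the stages,
with thresholds {2.5, 3, 3, 3, 3}).  The maternal "< 0.5 TPM" clause is
realised by default as a denominator floor — ratios are computed as
`num / max(den, 0.5)` — which keeps ratios finite and expresses the intent
that genes silent in oocyte/zygote and expressed later are de novo
transcribed.  An alternative reading, in which conditions only count when
some maternal stage is below 0.5 TPM, ships as `maternal_mode="gate"`;
both are defensible readings of the published rule and the choice is a
config switch, floor being the default.

Non-ZGA genes (the negative class for model training) have summed TPM
below 2 across the preimplantation stages; the MII oocyte is a maternal
sample, not an embryo stage, and is excluded from the sum.  Fold changes
for screening are simple pseudocounted ratios `(a + 0.01)/(b + 0.01)`;
differential-expression testing is deliberately out of scope.

Because a ratio can fire with a numerator as small as `floor × threshold`
(1.25 TPM), a gene can in principle satisfy both the ZGA and non-ZGA
definitions; the caller gives ZGA precedence so the two sets are disjoint.

## Feature extraction

**k-mer spectra.**  Each gene is represented by the k-mer frequency
spectrum of its TSS(−2 kb, +1 kb) and TES(−1 kb, +2 kb) flanks,
gene-strand oriented (the offsets are directional, so minus-strand genes
use the reverse complement; a reference-strand mode exists behind a flag).
Counts from the two flanks are summed into a single vector — model
features are plain words like TATATA with no region suffix — and divided
by the number of valid sliding windows, so clipped or N-containing regions
do not distort the scale.  All 4^k columns are kept in lexicographic
order; reverse complements are not collapsed, since e.g. ATATAT and TATATA
are distinct features.  Windows containing non-ACGT characters are skipped
rather than imputed.  k defaults to 6 and is configurable in [4, 8].

**Binned chromatin signal.**  Per-mark bedGraph coverage is summed into 20
bins of 300 bp across TSS ± 3 kb, bin 1 always the most upstream bin in
the direction of transcription (for minus-strand genes the reference-
coordinate bins over `[tss−3000, tss+3000)` are reversed; this convention
is off by one base relative to mirroring the half-open window itself,
which is irrelevant at 300 bp resolution and keeps the implementation a
pure reversal).  Bin sums are normalised to fragments per kilobase of bin
per million mapped fragments: `bin_sum / ((bin_width/1000) ×
(library_size/1e6))`, with `library_size` supplied as metadata.  Replicates
are averaged on the FPKM scale.  Columns are named `mark_i`, i = 1..20, so
bins 10/11 straddle the TSS.

## Learning

Positives are the called ZGA genes; an equal number of negatives is drawn
from the non-ZGA pool, and the balanced set is split 80/20 with
stratification.  Feature selection and hyperparameter search run strictly
inside the training split.

**MIC ranking.**  Features are ranked by the maximal information
coefficient against the class labels.  For a discrete binary label the
MINE grid search collapses to one dimension: the y-axis partition is the
two classes, so MIC is the maximum over x-axis partitions P (grid bound
`|P| × 2 ≤ B = n^0.6`) of `I(P(x); y) / log2 2`.  Mutual information is
additive over bins, so for each bin count the optimal partition is found
exactly by dynamic programming over tie-clumps; for large inputs adjacent
clumps are pre-merged into equal-frequency superclumps (the same
approximation MINE uses), 200 for the scalar scorer and 50 for the
vectorised whole-matrix scorer, which also breaks ties randomly under a
seed.  Constant columns score 0.  The implementation is checked against
exhaustive partition enumeration at small n.

**Incremental feature selection.**  Nested prefixes of the MIC ranking
(sizes 1..20 by default) are scored by stratified 10-fold CV accuracy of a
50-tree random forest; the best prefix wins, ties toward fewer features.
The cap of 20 reflects that roughly 20 features per final model makes five
shared words about a quarter of the modelled features.  The epigenetic
model skips selection and keeps the full mark × bin matrix: its
interpretation reads the top-ranked bins, and selection would only hide
them (with strongly separable marks the accuracy-driven prefix search
collapses to a single bin).

**Classifiers.**  Four algorithms: RBF-kernel SVM, random forest,
L2 logistic regression, and gradient boosting via XGBoost.
Hyperparameters come from a grid search (defaults: RF trees 100/300/500 ×
depth none/10/20; SVM C 0.1/1/10 × gamma scale/0.01; LR C 0.01/0.1/1/10;
XGBoost trees 100/300 × lr 0.1/0.05 × depth 3/6 — conventional values,
config-overridable) with stratified 10-fold CV on the training split,
model selection by mean CV accuracy.  Evaluation reports confusion counts
at probability 0.5, sensitivity, precision, accuracy, F1 (NaN with a flag
on zero denominators, never silent 0), the ROC curve over all thresholds
and its trapezoidal AUC.  AUC is independently cross-checked in the tests
against the Mann–Whitney U normalisation.

## Shapley attribution

Tree ensembles get exact path-dependent tree attributions: the value of a
coalition S is the tree expectation obtained by following the sample's
branch at splits on features in S and cover-weighting both branches
elsewhere; the per-feature Shapley values of this game are computed with
the polynomial-time extend/unwind path recursion for tree ensembles,
authored in-package (numba-compiled) and verified against brute-force
subset enumeration on small trees.  Attributions for random forests live
in class-probability space, so base value + contributions = predicted
probability to float precision.  XGBoost models use the library's native
`pred_contribs`/`pred_interactions` (the same algorithm, margin space).
SVM and logistic models use permutation-sampling Shapley against a
reference (default: training-split feature means; 2,048 permutations,
seeded) — each permutation's deltas telescope, so additivity to the
prediction is exact by construction and only the allocation among features
is stochastic.

Global importance is the mean |SHAP| over samples; the favourable /
unfavourable direction of a feature is the sign of the Pearson correlation
between feature value and attribution, with a ±0.2 dead zone (the
published rule is verbal; the threshold is configurable) and constant
features always indeterminate.  Pairwise interaction values for tree
models use the conditioned-recursion identity
`Φ(a,b) = (φ_b | a forced present − φ_b | a forced absent)/2`, symmetric
in (a, b); for non-tree models the operation raises, since only tree
structures admit exact interaction values here.

## Motif linking

Salient k-mers become PWMs with 0.997 at the consensus base and the
remainder spread evenly, exported in MEME minimal format (read and write
are both implemented; the reader is cross-checked against Biopython's
minimal-MEME parser in the tests).  The internal comparator scores every
offset with ≥ 5 aligned columns, both orientations, by the mean per-column
Pearson correlation — one of the published Tomtom column metrics — and
attaches an empirical p-value from ≥ 1,000 shuffled-query-column
permutations (add-one corrected, hence super-uniform under the null).
The exact Tomtom p-value machinery is not reimplemented; the MEME export
exists precisely so the external tool can be run when its statistics are
needed.

## Screening

The confidence report merges sequence score, epigenetic score and
per-dataset fold changes by gene id; absent epigenetic data stays absent
(NaN), never 0.  The default high-confidence rule is seq ≥ 0.6 AND fold
change ≥ 2 in at least two of the supplied datasets; the mouse rule
additionally requires epi ≥ 0.6, and an absent epigenetic score fails that
clause with the reason recorded in the trace.  For non-mouse species the
epigenetic clause is skipped, not substituted.  The evaluator is verified
against truth-table enumeration at the threshold boundaries and is
monotone: raising any score or fold change never revokes the flag.

## Synthetic data: what it emulates, and what it does not

The generator plants known structure so that every stage is testable
without downloads: one gene per fixed slot on a single chromosome (slots
sized so no two genes' windows can overlap), i.i.d. bases at a target GC,
random strands; Poisson-distributed copies of planted 6-mers (defaults
TATATA, ATTAAT, CTGCAG — TA-rich and CTGCAG-like words of the kind
over-represented in ZGA flanks; 8 copies per positive flank region vs 1
per negative) written non-overlappingly (rejection placement, so the
expected-count oracle stays exact) in gene-strand orientation; staged TPM
templates (maternal stages ≈ 0.1 TPM, activation stages ≈ 20 TPM for
positives, flat 0.1 for negatives — clearing every ruleset threshold with
margin) under multiplicative lognormal noise, with reject-and-resample of
any gene whose noisy profile would flip its label, so the generator never
emits truth inconsistent with its own caller; and Gaussian signal bumps
(centre −150 bp, FWHM 600 bp, amplitude 5 over background 0.5) for active
marks on positives and repressive marks on negatives, with positive
uniform background noise, optionally written as base-resolution bedGraph
that re-bins to the same matrix exactly.

What it does not emulate: linked genes and overlapping flanks, repeats and
base composition structure, transcriptome-wide correlation, read-level
artifacts, antibody efficiency or input bias, and partially informative
motifs embedded in degenerate families.  Passing the recovery benchmarks
therefore shows the chain is correct and sensitive under clean planted
signal, not that real-data AUCs or feature lists will be reproduced —
those depend on multi-GB public datasets outside desk scale.

## Benchmarks and problem sizes

The recovery benchmarks run the whole chain end to end: genome → planting
→ expression → caller → balanced split → featurization → MIC/IFS → grid
search → evaluation → attribution.  The sequence benchmark uses 400 genes
(≈ 200/200 after balancing), k = 6, ten seeds; recovery means test AUC
≥ 0.9 and every planted word in the SHAP top 10 in at least 8 of 10
seeds.  The epigenetic benchmark uses 300 genes, three marks × 20 bins,
ten seeds; recovery means AUC ≥ 0.9 and correct favourable/unfavourable
calls for every near-TSS bin (bins 9–12) reaching the top 20 ranks.
These sizes give stable recovery statistics while keeping a full
ten-seed sweep in the minutes range on one CPU.

## Numerical and degenerate-case choices

- Ratios and fold changes are floored/pseudocounted as above; no NaN or
  infinities can arise from zero TPM.
- Windows clipped at chromosome bounds are logged, counted windows shrink
  accordingly (frequencies still sum to 1), and fully clipped genes get a
  zero row plus a flag.
- Equal classifier scores collapse the ROC to the diagonal (AUC 0.5);
  undefined metrics are NaN plus a flag.
- MIC of a constant column is 0 by definition (no valid 2-bin partition).
- Zero-variance PWM columns (uniform background) contribute correlation 0
  to match scores; empirical p-values are add-one corrected so they are
  never 0.
- All randomness flows through `numpy.random.default_rng` seeds; repeated
  runs with the same seed are bit-identical, including FASTA/bedGraph
  output (bedGraph values are written at full float precision so
  round-trips are exact).

## Known limitations

- The MIC implementation is exact only for binary labels (all this
  package needs); continuous-vs-continuous MIC is out of scope.
- Path-dependent (not interventional) TreeSHAP is the tree attribution;
  the two differ on correlated features.
- Permutation-Shapley attributions for SVM/LR are Monte-Carlo: additivity
  is exact but per-feature allocation has sampling noise shrinking as
  1/√permutations.
- The internal motif comparator ranks sensibly and its empirical p-values
  are valid, but they are not Tomtom's analytic p-values.
- One annotated TSS per gene; alternative TSSs, repeat masking, peak
  calling and input correction are out of scope.
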
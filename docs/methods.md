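# Methods

## Problem setting

A panel of P component predictors assigns each of N proteins a categorical
subcellular location; a curated true location exists for training data.
Because component tools share input features, their errors are correlated,
and the practical question is which small subset of tools an ensemble
actually needs. `minens` implements three layers: a per-tool *contribution
score* (diagnostic), *minimalist subset selection* (pruning), and
*meta-classifier combination* (prediction), evaluated under stratified
cross-validation.

## Location mapping

Tools publish predictions in heterogeneous native vocabularies and at
different resolutions. All scoring operates on a unified vocabulary,
by default the five-location scheme Cytosol / Mitochondrion / Nucleus /
Secretory / Others. The built-in mapping hard-codes the documented CELLO
and WoLFPSORT native labels, applies the generic six-class secretory rule
(extracellular, plasma membrane, ER, Golgi apparatus, lysosomal, vacuolar →
Secretory), passes the four main compartment names through unchanged and
sends every remaining label to Others. The vocabulary is configurable, so a
high-resolution seven-location yeast scheme (Cytosol, Mitochondrion,
Nucleus, ER, Vacuole, Golgi, Cell Periphery) is expressible with a custom
mapping file. Matching is case-sensitive exact string comparison after
whitespace trimming. Missing predictions use the explicit sentinel `NA`;
rows containing `NA` are excluded from contribution scoring and subset
selection so vote counts remain well defined.

## Contribution score

For protein j let υmax be the size of the largest vote group, υsec the size
of the second-largest (0 if all tools agree), υcorrect the number of votes
equal to the truth, and υp(i) the number of tools voting the same label as
tool i (including i). Tool i's per-protein term is

    α·(2·υmax − υp(i)) + β·υsec + θ·(υcorrect − υp(i) − υmax)

with exactly one indicator active: α if correct and its vote group is
strictly smaller than the majority group, β if correct and in a (possibly
tied) largest group, θ if incorrect. A tie for the top count is treated as
membership of the majority group — a correct vote that merely ties the
crowd is not "lonely" and takes the β reward, not the α reward. Final
scores sum the per-protein terms over all proteins; normalised scores are
(CS − μ)/σ with μ, σ the mean and *population* standard deviation across
tools (all zeros when σ = 0, which avoids dividing by zero on degenerate
panels). Contribution scores are diagnostics: selection is done by CFS, not
by thresholding contributions.

## Minimalist selection

Tool outputs and the class are nominal, so correlation is measured by
symmetric uncertainty, SU(X,Y) = 2·I(X;Y)/(H(X)+H(Y)) with entropies in
bits, defined as 0 when H(X)+H(Y)=0. A subset S of size k is scored by the
CFS merit

    merit(S) = k·mean(r_cf) / sqrt(k + k(k−1)·mean(r_ff))

with r_cf the SU between each member and the class and r_ff the pairwise
member SU. The radicand is always ≥ k, so only the empty subset is
undefined. The search is greedy backward: start from the full panel and
repeatedly drop the tool whose removal leaves the highest-merit remainder,
recording every subset down to size 1; the recorded size-K subset is the
minimalist choice. Removal ties (merit difference < 1e-12) drop the
candidate with the lowest standalone r_cf, then the lowest column index —
deterministic, and biased toward keeping individually informative tools.
When selection runs inside cross-validation it is refitted on each fold's
training rows only. Baselines: top-K standalone accuracy (ties by column
order), and exhaustive enumeration of all size-K subsets scored by
cross-validated ensemble accuracy.

Note that an exact duplicate tool is *neutral* at k=2 (with r_ff=1 the
merit collapses to r_cf exactly) and harmful in larger subsets; the
backward search removes duplicates first either way.

## Ensemble schemes

All schemes consume the selected tools' categorical labels.

* **Weighted voting** — weight each tool by its training overall accuracy;
  predict the label with the largest weighted vote sum. Ties break by
  vocabulary order.
* **LDA-weighted voting** — per location c, a Fisher discriminant on the
  binary vote indicators [tool i votes c] separates proteins of class c
  from the rest; the discriminant direction supplies per-tool voting
  weights and an intercept, and the predicted location is the argmax of the
  per-location scores. The pooled covariance receives a small shrinkage
  term (default 1e-6) because coupled tools' vote indicators are nearly
  collinear. This is deliberately still a *voting* scheme: a vote for c
  only ever moves the score of c, so systematic cross-label error patterns
  are out of its reach.
* **Classifier schemes** — one-hot encode the labels (one binary column per
  (tool, label-observed-in-training) pair; unseen labels at predict time
  become an all-zero block) and fit multinomial logistic regression
  (L2, C = 1; mild regularisation prevents divergence on separable one-hot
  data and keeps the redundant encoding from overfitting), categorical
  naive Bayes with add-one smoothing, or a CART decision tree with minimum
  leaf size 2 and no depth limit.

Single-class training data is an error for LR and the LDA scheme. Fitted
models serialise to versioned JSON (scheme, vocabulary, encoder state,
weights / coefficients / probability tables / tree arrays); loaded models
predict through equivalent numpy routines, and round-trip prediction
equality is tested for every scheme.

## Evaluation

Overall accuracy is the fraction of proteins whose predicted unified label
equals the truth. MCC is computed one-vs-rest per location,
(TP·TN − FP·FN)/√((TP+FN)(TP+FP)(TN+FP)(TN+FN)), defined as 0 when any
denominator factor vanishes. Cross-validation uses seeded stratified fold
assignment (per-class shuffling with rotating fold offsets, so fold sizes
differ by at most one); a class with fewer members than folds triggers a
warning and simply cannot appear in every fold. Stratification matters
because realistic panels have locations with very few proteins. By default
an evaluated subset is held fixed across folds ("tested on" semantics);
`selection="cfs"` or `"topk"` instead re-selects inside each training fold
to avoid selection leakage. The experiment driver sweeps K and emits a tidy
table of (mode, scheme, K, subset, CV accuracy) covering the exhaustive dot
cloud, the minimalist line and the top-K baseline.

## Synthetic data

The generator emulates the statistical structure of a real predictor panel
without simulating sequences. Truth is drawn from configurable class
priors. Predictors belong to *feature groups*; per protein each group draws
one shared pair of uniform variates, and each member copies the group draw
with probability ρ (default 0.9), otherwise drawing privately. A draw is
correct when the uniform falls below the member's own per-class recall, so
marginal accuracies stay exactly at the configured recalls while ρ tunes
how strongly group members are right and wrong together (ρ=1 with identical
specs gives identical columns; ρ=0 gives conditional independence given the
truth). Wrong predictions take a label from the member's confusion row
(default: uniform over non-true classes); coupled members share the error
draw, so redundant tools also agree on *which* wrong label they output.
Replicate experiments use seed = base + replicate index; a single seeded
stream drives each table.

Two built-in profiles mirror the published yeast and human benchmark
panels: class priors follow the benchmark class counts (yeast 498/175/234/
315 of 1222; human 361/327/159/458 of 1305), and each predictor's
prior-weighted mean recall equals the corresponding tool's published
overall accuracy. Per-class recall shifts encode the documented strengths —
sequence-feature tools strong on Mitochondrion and Secretory and weak on
Cytosol, the PPI analog strongest on Nucleus — and structured confusion
rows encode systematic failure modes (sequence tools default toward
Cytosol when they fail; the PPI analog errs toward the heavily connected
nuclear/cytosolic compartments). The yeast profile has three information
sources: the PPI analog (independent of everything), a sequence-feature
group hosting the signal-based tools *and* the homology analog (the
multi-feature signal tools perform homology search themselves, so a
homology-only tool is not an independent source), and a coupled
amino-acid-composition group. The human profile is the same panel without
the PPI analog.

These choices were fixed by a forward design pass against the documented
qualitative structure — an independent-source tool earns the top
contribution score and survives minimalist selection; a 3-predictor
minimalist ensemble is comparable to the full panel; scheme ordering
LR ≥ LDA-voting ≥ accuracy voting, with voting degrading as redundant
low-accuracy tools pile up. Two of them are load-bearing: high ρ (strong
within-group redundancy) is what makes small subsets competitive, and
structured (non-uniform) confusion is what gives the classifier schemes
learnable cross-label rules; with uniform confusion the voting constraint
costs nothing and LDA-voting matches LR.

What the generator does *not* model: multi-location proteins, missing
predictions from server failures (`NA` handling is tested separately),
heavy-tailed per-protein difficulty shared across *all* tools, and any
dependence of errors on sequence properties. Passing tests therefore show
that the pipeline recovers planted redundancy/complementarity structure of
this specific form — not that any particular real tool panel will prune to
three members.

## Numerical conventions

* Entropies in bits; mutual information clipped at 0 and SU capped at 1
  against floating-point drift.
* Greedy-removal merit ties resolved within 1e-12 as described above.
* All prediction-time ties (vote sums, equal discriminant scores, equal
  posteriors) break by label-vocabulary order.
* TSVs are tab-delimited UTF-8 without quoting, so write→read round trips
  are byte-exact; tables compare by exact string equality.
* Problem sizes in the test suite: structure-recovery checks use 50
  replicates at n=1000; scheme-ordering checks 20 replicates at n=1000
  with 10-fold CV; exhaustive-search dominance uses a 6-predictor panel at
  n=300 with 5-fold CV. These sizes give stable means for the effects being
  checked (differences of one percentage point and larger).

## Known limitations

* The built-in location mapping covers only the documented CELLO and
  WoLFPSORT native vocabularies plus the generic rules; other tools need a
  user-supplied mapping file.
* The backward greedy search is not guaranteed to find the best subset of
  a given size (the exhaustive baseline exists precisely to measure that
  gap), and the original CFS locally-predictive post-processing heuristics
  are deliberately not implemented.
* LDA-weighted voting fits one discriminant per location independently;
  locations absent from a training fold score −inf and can never be
  predicted by that fold's model.
* Contribution scores depend on the whole panel's composition: they rank
  tools within a panel and are not comparable across panels.
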
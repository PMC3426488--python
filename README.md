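# minens — minimalist ensemble design for protein subcellular localization

Dozens of computational tools predict the subcellular compartment of a
protein (nucleus, mitochondrion, cytosol, secretory pathway, ...) from its
sequence or interaction partners. Ensemble predictors that combine many such
tools usually improve accuracy, but most of the component tools lean on the
same input features — amino-acid composition above all — so their predictions
are heavily redundant: adding more tools adds cost, web-server round trips
and overfitting risk while contributing little new information. `minens` is
a toolkit for *pruning* such ensembles down to a minimal complementary
subset, for people building meta-predictors from categorical tool outputs:

* **Contribution scores** quantify each tool's unique value. For protein *j*
  with majority-vote count υ<sub>max</sub>, second-majority count
  υ<sub>sec</sub>, correct-vote count υ<sub>correct</sub> and agreement
  count υ<sub>p(i)</sub> (tools voting like tool *i*, itself included),
  tool *i* earns

  α<sub>ij</sub>·(2υ<sub>max</sub> − υ<sub>p(i)</sub>) + β<sub>ij</sub>·υ<sub>sec</sub> + θ<sub>ij</sub>·(υ<sub>correct</sub> − υ<sub>p(i)</sub> − υ<sub>max</sub>)

  where exactly one indicator fires: α (correct and in the minority),
  β (correct and in the majority), θ (incorrect). Correct-but-lonely votes
  score highest; wrong votes cast with the majority score lowest. Scores are
  summed over proteins and z-normalised across tools, (CS − μ)/σ.
* **Minimalist subset selection** treats the tools' categorical outputs as
  nominal features and runs a greedy backward search under the CFS merit
  k·r̄<sub>cf</sub> / √(k + k(k−1)·r̄<sub>ff</sub>), with symmetric
  uncertainty 2·I(X;Y)/(H(X)+H(Y)) as the correlation measure: keep subsets
  whose members correlate with the true location but not with each other.
  Top-K-accuracy selection and exhaustive subset search are included as
  baselines.
* **Meta-classifier ensembles** combine the selected tools' labels:
  accuracy-weighted voting, LDA-weighted voting, categorical naive Bayes,
  CART decision trees and multinomial logistic regression, all exposed as a
  scikit-learn compatible `EnsembleClassifier` (plus `CFSBackwardSelector` /
  `TopKAccuracySelector` transformers).
* **Evaluation** by overall accuracy and one-vs-rest Matthews correlation
  per location under seeded stratified k-fold cross-validation, with an
  experiment driver for accuracy-versus-K sweeps.
* **A synthetic-data generator** emulates panels of redundant and
  complementary predictors (feature-group-coupled errors, class-dependent
  recalls, structured confusion), so the whole pipeline is testable without
  querying any real prediction server.

## Worked example

Simulate a yeast-like panel of nine predictors over four locations, score
contributions, select a minimalist subset and evaluate it:

```sh
$ minens simulate --profile yeast_lowres --n 1000 --seed 42 --out demo.tsv
simulated 1000 proteins x 9 predictors -> demo.tsv
$ minens score --table demo.tsv --out demo_scores.tsv
$ cat demo_scores.tsv
predictor       raw_score       normalized_score
NetLoc_like     306     2.55682
YLoc_like       -3016   -0.602799
MultiLoc2_like  -1780   0.572786
WoLFPSORT_like  -2548   -0.157675
KnowPred_like   -2436   -0.0511491
Subcell_like    -3418   -0.985149
BaCelLo_like    -2942   -0.532416
CELLO_like      -2497   -0.109167
SubLoc_like     -3109   -0.691253
```

`NetLoc_like` — the panel's only predictor whose errors are independent of
everyone else's (it emulates a protein–protein-interaction-based tool) — is
the lone predictor with a *positive* raw score: it is frequently right when
the sequence-based majority is wrong. The composition-based tools sit at the
bottom: their correct predictions are almost always covered by others.

```sh
$ minens select --table demo.tsv --k 3 --out demo_subset.txt
selected: NetLoc_like, MultiLoc2_like, CELLO_like
$ minens evaluate --table demo.tsv --subset demo_subset.txt --scheme lr \
    --folds 10 --seed 7 --report demo_report.json
overall accuracy: 0.6820
MCC Cytosol: 0.4306
MCC Mitochondrion: 0.7788
MCC Nucleus: 0.3220
MCC Secretory: 0.6937
```

The CFS search keeps one representative per information source (PPI, the
signal-feature group, the composition group). Three predictors reach 0.682
cross-validated accuracy versus 0.724 for all nine on this seed; averaged
over replicates the difference is under two percentage points (the test
suite checks this), while two thirds of the panel — and their server
queries — are dropped. Every component alone stays below 0.58.

The same operations are available as library calls (`contribution_scores`,
`select_minimalist`, `cross_validate`, ...) on `PredictionTable` objects,
and `EnsembleClassifier`/`CFSBackwardSelector` slot into sklearn pipelines.

Real tool outputs use heterogeneous location names; `minens.builtin_mappings`
collapses them onto the unified five-location vocabulary (Cytosol,
Mitochondrion, Nucleus, Secretory, Others), including the documented CELLO
and WoLFPSORT native labels and the generic six-class secretory rule.

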
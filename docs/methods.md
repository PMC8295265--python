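# Methods

This note documents the models implemented in `disofun`, the choices made
where the design was genuinely open, what the synthetic-data generator does
and does not emulate, and the package's known limitations.

## The prediction architecture

Prediction proceeds in three steps per protein chain: a per-residue
**profile**, a three-level **feature encoding**, and two **machine-learning
stages** (disorder, then disorder function) whose outputs are aligned by
construction.

### Profile

The profile is a length-L × 45 matrix. The package consumes profile rows
from TSV tables; it does not run any upstream sequence-analysis tool. Three
quantities are computed in-house:

* **PSSM scaling.** Raw substitution scores are squashed elementwise with
  the logistic `1/(1+e^{−x})` so all channels share the [0,1] range.
* **Conservation.** A PSSM row `s` is softmax-normalised to a probability
  vector `p` over the 20 amino acids and scored `1 − H(p)/ln 20` (Shannon
  entropy in nats). The score is 0 for a flat row, approaches 1 as mass
  concentrates on one letter, and is invariant to adding a constant to the
  row. This is a standard entropy-based conservation definition chosen for
  boundedness, monotonicity and testability.
* **Physicochemical scalars.** Kyte–Doolittle hydropathy, net formal charge
  at neutral pH, Grantham polarity and residue volume, each min–max scaled
  to [0,1] over the 20 letters (X receives the scaled mean). These fill the
  schema with sequence-only channels requiring no external tool.

The 45-channel breakdown (20 PSSM + 1 conservation + 6 secondary structure
+ 4 baseline disorder + 10 function predictors + 4 physicochemical) is the
package's documented default; the schema object is configurable, so an
alternative breakdown with the same channel count can be swapped in. The
channel count is pinned by the encoder arithmetic below: with residue window
5 the total feature count must satisfy `7P + 3 = 318`, hence `P = 45`.
Whether the upstream predictors contribute one or two disorder modes, or
binary tracks alongside propensities, is an open choice; the default
includes both modes and the binary tracks.

### Encoding

For residue *i*:

* **Residue level** — raw profile rows at the `r` positions centred on *i*
  (`r = 5` for the disorder task, `1` for the function task).
* **Window level** — per-channel arithmetic mean over the `a` positions
  centred on *i* (`a = 15` disorder, `11` functions).
* **Protein level** — per-channel whole-chain means, a length feature
  `min(L, 10000)/10000`, and the normalised terminus distances `(i−1)/L`
  and `(L−i)/L`.

Feature counts: `rP + P + (P+3)` → 318 (disorder) and 138 (functions).

Numerical choices at the boundaries: out-of-range window slots are filled
with the **protein-level channel mean**, not zero. Zero-fill would fabricate
a "low signal" band at the termini; mean-fill keeps two exact invariants
used by the tests — a constant profile encodes to constant channel features,
and a window covering the whole chain reproduces the protein-level mean
exactly. The length cap and the per-chain normalisation of terminus
distances keep all features bounded; no further standardisation is applied
because every channel already lives in [0,1].

### Disorder models

`DisorderNet` is a feedforward network: input 318 → dropout 0.2 → 64 ReLU →
dropout 0.2 → 8 ReLU → 1 sigmoid. It is implemented directly in numpy,
which keeps training exactly reproducible from a single seed (weight
initialisation, minibatch order and dropout masks all derive from it).
Training controls, with defaults: Adam (learning rate 1e-3), minibatch 256,
binary cross-entropy with inverse-class-frequency sample weights (disorder
is typically the minority class), at most 200 epochs, early stopping on
validation ROC-AUC with patience 10; the best-epoch weights are kept.
`DisorderLogistic` is the logistic-regression twin on the identical feature
matrix.

Binary calls use the strict rule `propensity > t`. The threshold *t* is
chosen on validation data to maximise F1 over the candidate set of all
unique predicted propensities, ties going to the smaller candidate. Note a
consequence of the strict inequality: the residue carrying the minimum
propensity can never be called positive when candidates are restricted to
observed propensities.

Grid search over network configurations ranks by validation AUC, breaking
ties toward fewer parameters and then earlier grid position.

### Function models

One random forest per function (protein binding, DNA binding, RNA binding,
linker). The training universe is the set of residues the disorder model
calls disordered; positives are those inside a region annotated with the
function, negatives the rest of that universe (the annotation data define
no explicit negatives, so "predicted-disordered but not annotated" is the
natural complement). Hyper-parameters — number of trees over {100, 250,
500} and depth over {5, 10, ∞} by default — are selected by mean ROC-AUC
under stratified 3-fold cross-validation; the threshold maximises F1 on the
winning point's out-of-fold predictions; the final forest is refit on all
rows.

At prediction time, function propensities and binaries are reported only
inside predicted IDRs and are exactly 0 outside. Reporting 0 rather than a
masked/absent value keeps the per-residue CSV rectangular; the binary track
carries the same information. This masking is what guarantees the alignment
invariant: **no residue is ever function-positive and disorder-negative**,
for any input and any models.

## Evaluation protocol

Metrics are pooled over the concatenated residues of all proteins (a
per-protein-averaged variant exists, clearly non-default). ROC curves
threshold at every unique propensity; AUC is trapezoidal and equals the
positive–negative pair-ordering probability with half credit for ties (the
test suite checks this against a brute-force oracle). MCC/F1/TPR/FPR come
from explicit confusion counts; a zero MCC denominator yields MCC = 0 with
a degeneracy flag instead of NaN.

A protein is *fully disordered* when disordered residues cover **≥ 95%** of
its sequence; the same fraction rule applied to predicted binaries gives
the protein-level prediction. The boundary is inclusive (19 of 20 residues
qualifies) and the comparator is configurable.

Significance of a difference between two predictors is assessed by drawing
⌊N/2⌋ proteins without replacement 10 times (the same half for both
predictors — a paired design), recomputing the metric per replicate, and
testing the 10 paired differences: a two-sided paired t-test when an
Anderson–Darling test at 0.05 does not reject normality of the differences,
otherwise a two-sided Wilcoxon signed-rank test. All-zero differences (for
example, a predictor compared with itself) report p = 1 with a degeneracy
flag rather than erroring. A replicate whose half-sample contains a single
label class is redrawn and recorded in the report.

**Limitation — anticonservatism under a global null.** The 10 half-samples
of a fixed test set overlap, so the 10 paired differences are not
independent draws centred on zero: they concentrate around the two fixed
predictors' full-dataset difference, which is nonzero by chance alone. The
package's own Monte-Carlo calibration experiment (in the acceptance tests:
200 comparisons of two independent uniformly-random predictors on 60
proteins of length 80) measures a type-I error far above the nominal 5%
level at α = 0.05. The procedure is therefore best read as "is the observed
difference on *this* dataset robust to halving it", not as a calibrated
test that two predictors are equivalent in population. The implementation
deliberately follows the procedure as specified; users wanting calibrated
nulls should use disjoint splits or permutation tests instead.

## Ablation machinery

Six configurations, each deleting exactly one component and retraining from
scratch under the same seed regime: the function-predictor channels, the
protein level, the window level, the residue level, the 20 PSSM channels,
or the 4 baseline-disorder channels. Feature counts follow the closed form
(248, 270, 273, 93, 178, 290 for the default schema). The conservation
channel is kept as its own schema group and survives the PSSM ablation,
which keeps the PSSM removal at exactly the 20 substitution-score channels.
Hyper-parameters are not retuned per configuration. The result table always
contains the untouched model as row `full`, and each ablation row carries
resampling p-values against it.

## Synthetic-data generator

Per protein: length uniform in a range; a disorder track from a two-state
Markov chain with stay probabilities `p_stay_disorder`/`p_stay_order`
(geometric segment lengths, stationary disorder fraction
`(1−p_stay_order)/((1−p_stay_order)+(1−p_stay_disorder))`), or an
all-disordered chain with probability `fully_disordered_fraction`; a
per-protein bias `b ~ N(0, protein_bias_sd)` added to every informative
channel; informative channel values `clip01(effect·label + b + N(0,
noise_sd))`; physicochemical channels computed from the (uniformly random)
sequence; all remaining channels Uniform(0,1); function regions carved as
contiguous sub-intervals of disordered segments with a per-segment coverage
probability, so function annotations are always subsets of disorder — as in
curated data. Clipping (rather than a logistic squash) preserves the linear
effect structure so the logistic twin remains comparable to the network.

The per-protein bias term is the deliberate reason protein-level features
matter: the chain-average of an informative channel estimates `b` (plus the
disorder fraction), letting a model subtract the offset from the local
values. The `protein_level_signal` fixture sets a large bias (sd 0.4)
against a moderate effect (0.4) and long disorder segments (mean 20
residues, comparable to the 15-residue window), so neither the residue nor
the window level can de-confound locally — removing the protein level then
costs the most, which is exactly what its acceptance test asserts.

Fixture conditions (fixed at design time): `separable` — 200 proteins,
lengths 60–200, one channel carrying effect 0.8 at noise sd 0.1;
`null` — 120 proteins, no effects; `protein_level_signal` — 200 proteins as
above; `function_toy` — 160 proteins, one informative channel per function
(effect 0.8, per-segment coverage 0.6) plus a separable disorder channel.

What the generator does **not** emulate: the amino-acid compositional bias
of real IDRs, realistic PSSM score distributions, correlations among the
upstream predictors, or annotation noise. Passing tests on these fixtures
therefore demonstrate that the machinery learns and evaluates what it
claims to — not that the trained models would reach any particular accuracy
on curated disorder data.

## Problem sizes used in the test and acceptance runs

Tests train on the fixture corpora described above (≤ 200 proteins,
~15k–26k residues), with epoch caps of 30–60 and single-point forest grids
where a full grid search is not itself under test. These sizes were chosen
so the planted signals are comfortably recoverable while the whole suite
remains quick on one CPU.

## Known limitations

* The network trains on a CPU in numpy; it is intended for corpora of
  hundreds to thousands of proteins, not proteome-scale training.
* The profile schema fixes one plausible 45-channel breakdown; real
  deployments would need the upstream tools' outputs mapped into it.
* The resampling significance procedure is anticonservative under a global
  null (see above).
* Only the four best-annotated disorder functions are modelled; lipid,
  metal and small-molecule interactions are out of scope.
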
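# Methods

## The prediction problem

Each adverse-event report is a tuple *(d, m, a, g, w, q, t; s)*: a set
of diseases (indications), a set of drugs, age in years, sex (1 male,
2 female), weight in kilograms (often missing), reporter qualification
(1 physician … 5 consumer), a report date, and the observed ADR set
*s*, which is the multi-label target. Prediction is per patient over a
fixed ADR vocabulary: given a new patient's diseases, candidate drugs
and demographics, score every ADR in the vocabulary.

## The Adverse Event Report graph

Nodes are patients, diseases and drugs. Each training report
contributes one patient node, `has_disease` edges to its diseases and
`takes` edges to its drugs, plus exact reverse edges so messages flow
both ways. Patient features are a bag-of-words multi-hot over the
disease and drug vocabularies followed (by default) by a 10-entry
demographic block `[age/100, sex one-hot(2), weight/100 (0 if missing),
weight-missing flag, qualification one-hot(5)]`; disease and drug
features are one-hot.

ADRs are deliberately **not** nodes. The vocabulary, the graph, and the
label matrix are built from training reports only; held-out patients
are attached afterwards with their disease/drug edges and features but
never their ADR sets. Had patient–ADR edges been part of message
passing, training labels would leak into the representations of
neighboring patients and the inductive evaluation would be broken; the
ADR space exists only as the |S|-dimensional output layer. A byte-level
scan test on serialized graphs confirms no held-out ADR information
enters the archive.

Entities unseen in training are dropped (with a warning) when attaching
new patients: the label and feature spaces are frozen at training time.

## Encoder

A heterogeneous graph transformer. Per layer and head *i*:

* typed projections: `K_i(s) = K-Linear_τ(s),i(H[s])`, likewise `Q_i(t)`
  and the message projection `M-Linear`;
* per-edge-type bilinear attention
  `ATT_i(s,e,t) = (K_i(s) W_ATT^φ Q_i(t)ᵀ) · μ_⟨τ,φ,τ⟩ / √d_h`, softmax
  over **all** incoming edges of each target node jointly across edge
  types;
* messages `MSG_i(s,e,t) = M_i(s) W_MSG^φ`, heads concatenated;
* aggregation: attention-weighted sum, then a target-type output
  projection, GELU, and a residual connection. Nodes with no incoming
  edges keep their representation unchanged.

Inputs are first projected per type and LayerNorm-ed. The attention
divisor is √d_h (per-head width), the conventional transformer scaling;
a literal divisor of *d* can be selected via
`HGTConfig(attention_scale="d")` for comparison. μ is initialized to 1,
linear maps Xavier-uniform, under a caller-supplied seed.

Defaults are `d=64`, `h=4`, `L=2`. These are package choices (the
architecture sizes are not externally fixed) and are exposed as
estimator parameters; the ablation harness sweeps them.

Correctness is established against a brute-force dense oracle — an
independent implementation with explicit Python loops over nodes, edges
and heads — which agrees with the vectorized encoder to 1e-5 on random
toy heterographs, and by permutation-equivariance and
attention-normalization property tests.

## Augmentation branch, predictor, objective

The augmentation view is `H_P^S = GELU(FC(Aug(X_P)))` with
`Aug(X) = X + (E − Dropout(E, ε))`, `E ~ N(0, σ²)` i.i.d., dropout rate
ε (zeroed entries, survivors scaled by 1/(1−ε)). At evaluation Aug is
the identity. Defaults ε = 0.5, σ = 0.1 (the distribution of E is a
package choice; zero-mean Gaussian with configurable σ).

The predictor is `Ỹ = sigmoid(FC(H_P^L + H_P^S))`: independent
per-ADR probabilities (multi-label; no softmax across ADRs).

The focal loss is the standard per-entry focal binary cross-entropy

    −[ Y (1−p)^γ log p + (1−Y) p^γ log(1−p) ],

averaged over all (patient, ADR) entries, probabilities clamped to
[1e-7, 1−1e-7]. The one-sided form −(1−Y)^γ log Ỹ is not a usable
multi-label loss (it is undefined on negative entries); the per-entry
focal BCE reduces to it on positives and is the standard reading of
"p is the predicted probability of the correct class". γ defaults to 2.

InfoNCE uses cosine similarity with temperature T (default 1; the
similarity function is a package choice), over a batch of B patients
(default 256, drawn fresh each epoch): the two views of the same
patient are the positive pair, other patients in the batch the
negatives. Identities `L(B=1)=0` and `L = ln B` for identical rows are
asserted in tests. The combined objective is
`L = α·L_InfoNCE + (1−α)·L_focal`, α default 0.1.

## Training loop

Full-batch Adam (default lr 1e-3) with optional decoupled weight decay
on weight matrices only (biases and LayerNorm parameters are not
decayed). Early stopping monitors macro-AUC on a validation split
attached inductively to the training graph, with configurable patience
and evaluation cadence; the learning rate is halved once after half the
patience is exhausted, and the best-validation parameters are restored.
An optional Polyak (EMA) average of the weights can be used for
evaluation (`ema_decay > 0`); it is off by default. The predictor bias
is initialized to the per-ADR log-odds of the training prevalence — the
standard prior-probability initialization for rare positives. Gradients
of the full objective are exact (reverse-mode autodiff in
`preciseadr._autodiff`) and validated against central finite
differences to 1e-4 relative error on a 5-patient model.

All randomness (initialization, augmentation noise, InfoNCE batches)
derives from a caller seed; two runs with the same seed reproduce the
same trajectory bit-for-bit.

## Signal mining

The screening pipeline: **quality control** keeps reports from health
professionals (qualification 1–3 by default) with complete age and sex;
**drug interference** keeps reports with ≥1 drug, ≥1 ADR, and an ADR
set disjoint from the disease set (an event that merely restates an
indication is not a drug event); **association mining** then tests each
ADR occurring ≥ `min_count` times with a Pearson chi-square (no
continuity correction) on the report-level strata × present/absent
table — sex for gender, child &lt;18 / adult 18–64 / elderly ≥65 for age
— with Benjamini–Hochberg adjustment across tested ADRs. An ADR is
flagged only when q ≤ α, every expected cell count is ≥ 5, and an
effect-size floor holds: |log OR| ≥ log 1.5 for 2×2 tables, and for
multi-stratum tables the largest one-stratum-vs-rest |log OR| (the
multi-stratum floor is a package choice; all thresholds configurable).
Degenerate tables (a zero margin or a single occupied stratum) are
skipped with a log entry, not an error.

This is a screening statistic in the spirit of routine
disproportionality practice, not a causal analysis; drug-stratified
drilldowns are reporting queries, not tests. On null cohorts the mean
flagged fraction is well under the FDR level (measured ≈ 0.003 at
α = 0.05 over 20 cohorts of 5,000), and planted gender effects with
odds ratio 3 and prevalence ≥ 2% are recovered with sensitivity 1.0 at
n = 20,000.

## Synthetic cohorts: what they emulate and what they do not

`generate_cohort` draws, per patient: sex ~ Bernoulli(p_female)+1 (0.6
female, reporting skew); age from a child/adult/elderly Gaussian
mixture (N(9,4) w=0.1, N(42,12) w=0.6, N(74,7) w=0.3, truncated to
[0,100]); 1+Poisson(1) diseases from a Zipf(1.2) popularity prior;
1+Bernoulli(0.5) drugs per disease from that disease's 4-drug candidate
menu (menus drawn once per world from popularity weights). Each ADR is
then present with probability

    sigmoid(β0_s + Σ_{m∈drugs} β_{m,s} + λ^g_s·1[female] + λ^a_{s,group}),

OR-ed with a spurious-mention noise process (rate 0.01). Patients with
no ADR are discarded and resampled — a safety report by construction
contains an event — which preserves the conditional model for retained
reports; calibration tests verify prevalence against sigmoid(β0) after
correcting for this filter.

`please_like_spec(scale)` scales the full-cohort dimensions (279,299
reports; 889 ADRs; 1,059 diseases; 978 drugs) by `scale` (floor 10) and
plants: 3 causal drugs per ADR at log-OR 2, drawn
popularity-weighted — reporting databases carry signal on commonly used
drugs, and min-count curation guarantees exposure support; without this
the planted pairs would sit on drugs that are almost never prescribed
and the cohort would be nearly signal-free (Bayes-oracle macro-AUC
≈ 0.59, versus ≈ 0.74 with exposure-weighted placement, in line with
the discriminability real report data exhibits). 10% of ADRs are
gender-related (|OR| = 3, random sign) and 15% age-related (elderly
OR = 3, child OR = √3) by default; both fractions and effect sizes are
parameters. The world seed is fixed and documented (12345): the planted
world is part of the study conditions, while experiment seeds vary
splits and training.

The generator does **not** emulate: drug co-prescription correlation
beyond shared indications, temporal dosing, report duplication,
ontology structure among terms, or reporting-propensity biases beyond
the demographic effects themselves. Passing recovery tests therefore
show that the pipeline recovers logistic planted effects of realistic
size from realistically skewed multi-label data — not that it would
match any particular real-data figure.

## Evaluation conventions

* **macro-AUC**: per-ADR tie-corrected rank AUC (Mann–Whitney U /
  (n₊n₋)) over evaluable ADRs (≥1 positive and ≥1 negative test
  patient), unweighted mean. Under this convention any per-ADR-constant
  scorer — e.g. the marginal frequency baseline — scores exactly 0.5,
  which pins the convention down. Micro (pooled) AUC is reported
  alongside.
* **Hit@10**: fraction of test patients (with ≥1 true ADR) whose top-10
  scored ADRs contain a true one; ties break by ADR index. Recall@10 is
  a secondary column. At small ADR vocabularies (≲ 20) Hit@10
  saturates; it is discriminative at larger |S|.
* **Frequency baselines**: uniform-random; marginal; conditional on
  indications and/or drugs with Laplace (+1 / +2) smoothing, averaged
  over the patient's entities, with marginal fallback for patients
  whose entities are all unseen.
* **Drug-only MLP**: two-layer perceptron on the drug multi-hot block
  alone, focal BCE — the drug-level reference point.
* **Perturbations**: gender flips 1↔2 (an involution); age permutes
  ages across test patients, preserving the marginal age distribution
  (chosen over resampling or shifting precisely because it is
  distribution-preserving); both applies both. Labels and exposures are
  untouched.

## Study problem sizes

The canned experiments in `preciseadr.experiments` use desk-scale
cohorts chosen to keep each experiment in the minutes range on one CPU
while leaving the tested effects comfortably identified:

* end-to-end recovery: 2,000 patients, 50 ADRs, drug effects plus
  dominant demographic effects (40% of ADRs gender-related, 40%
  age-related, OR 4 — the regime where patient-level context matters
  most); encoder d=64, γ=0.5, α=0.1, lr 1e-2, weight decay 1e-2.
  γ below the generic default improves ranking here because with
  50 well-populated ADR columns the focal down-weighting of easy
  negatives is unnecessary; γ remains a swept parameter.
* perturbation: five 1,200-patient gender-driven cohorts (half the
  ADRs at OR 6), d=32; the gender-flip AUC drop on gender-related ADRs
  is measured per seed.
* ablation: 1,000 patients, training fractions {0.25, 0.5, 1.0} × 3
  seeds, d=32; the training-size/AUC association is summarized by a
  Spearman correlation, reported rather than asserted inside the
  harness.
* mining calibration: 20 null cohorts of 5,000 filtered reports;
  power: one 20,000-report cohort with eight planted OR-3 ADRs.

## Known limitations

* Full-batch numpy training: fine for 10³–10⁴ patients, not for
  millions; no neighbor sampling or minibatched message passing.
* The chi-square screen tests marginal demographic association at
  report level; confounding by indication or drug exposure is by
  design not adjusted for.
* Real vocabularies (MedDRA/DrugBank) and raw FAERS archives are not
  parsed; IDs are opaque strings and the TSV/JSONL schema is the
  interchange format.
* Hit@10 and macro-AUC averaging conventions are stated choices; other
  conventions (recall@10, patient-averaged AUC) would give different
  absolute numbers.
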
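# preciseadr

Patient-level adverse drug reaction (ADR) prediction from spontaneous
adverse-event reports, plus the statistical screening that motivates it.

Spontaneous-reporting systems such as FAERS collect reports of the form
*(diseases d, drugs m, age a, sex g, weight w, reporter qualification q,
date t) → observed ADRs s*. Classical pharmacovigilance models predict
side effects per **drug**; this package predicts them per **patient**,
so that two patients on the same drugs but with different comorbidities
and demographics get different risk profiles.

The core model is a heterogeneous graph transformer (HGT) over an
**Adverse Event Report graph**: patient, disease, and drug nodes, with
`has_disease` / `takes` edges (and exact reverses) built from training
reports only. Each layer computes, per edge (s, e, t) and head i,

    ATT_i(s,e,t) = (K_i(s) W_ATT^φ(e) Q_i(t)ᵀ) · μ_⟨τ(s),φ(e),τ(t)⟩ / √d_h
    MSG_i(s,e,t) = (M-Linear_τ(s),i H[s]) W_MSG^φ(e)
    H'[t]        = H[t] + GELU(A-Linear_τ(t)( Σ_e ATT·MSG ))

with attention softmax-normalized over all incoming edges of each
target. A parallel augmentation branch encodes noise-perturbed patient
features, `Aug(X) = X + (E − Dropout(E, ε))`, through one FC layer; the
predictor scores all ADRs from the sum of the two views. Training mixes
a multi-label focal binary cross-entropy with an InfoNCE term that
aligns the two views of the same patient:

    L = α·L_InfoNCE + (1−α)·L_focal

New patients are scored **inductively**: attached to the trained graph
by their diseases and candidate drugs, without labels and without
retraining.

Around the model, the package provides

* a synthetic FAERS-like cohort generator with planted drug→ADR and
  demographic effects and full ground truth (`preciseadr.simulate`),
* the demographic signal-mining pipeline — quality control, drug
  interference filtering, per-ADR chi-square tests with
  Benjamini–Hochberg FDR (`preciseadr.mining`),
* frequency and drug-only-MLP baselines, macro-AUC / Hit@10 metrics,
  demographic-perturbation experiments and a training-size ablation
  harness (`preciseadr.evaluate`, `preciseadr.experiments`).

The neural components run on a small reverse-mode autodiff core
(`preciseadr._autodiff`, numpy-based, validated against finite
differences), so the package has no deep-learning framework dependency.

## Worked example

```python
import preciseadr as pa

# a scaled FAERS-like cohort: ~5,600 reports, 18 ADRs, planted effects
spec = pa.please_like_spec(scale=0.02)
reports, truth = pa.generate_cohort(spec)

train, val, test = pa.split_cohort(reports, (0.8, 0.1, 0.1), seed=0)
model = pa.PreciseADR(d=32, lr=1e-2, weight_decay=1e-2,
                      max_epochs=150, patience=10, eval_every=5)
results = pa.run_experiment(reports, model, seed=0,
                            baselines=("marginal", "given_drugs"))
for name, r in results.items():
    print(f"{name:12s} macro-AUC {r.macro_auc:.4f}  Hit@10 {r.hit_at_10:.4f}")
```

prints (seed 0)

```
preciseadr   macro-AUC 0.7586  Hit@10 0.9749
marginal     macro-AUC 0.5000  Hit@10 0.9731
given_drugs  macro-AUC 0.7050  Hit@10 0.9677
```

The marginal ADR-frequency baseline scores exactly 0.5 by construction
(its scores are constant across patients within each ADR); the graph
model beats the strongest conditional-frequency baseline by exploiting
disease context and demographics. Hit@10 saturates on this small
18-ADR vocabulary — with 10 of 18 candidates almost every patient's
top-10 contains a true ADR — and becomes discriminative at larger
vocabulary sizes.

Mining demographic signals from the same cohort:

```python
filtered = pa.drug_interference_filter(pa.quality_control(reports))
records = pa.mine_gender_associations(filtered, alpha=0.05, min_count=50)
print(pa.summarize_signals(records))
```

```
  attribute  tested  flagged
0    gender      18        2
```

Both flagged ADRs are among the cohort's planted gender-related ADRs
(`truth.gender_related_adrs`).

A command-line interface mirrors the library:

```bash
preciseadr simulate --scale 0.02 --seed 7 --out cohort.tsv --truth truth.json
preciseadr mine     --reports cohort.tsv --attribute gender --out signals.tsv
preciseadr evaluate --reports cohort.tsv --seed 0 --out results.tsv
preciseadr perturb  --reports cohort.tsv --mode gender --seed 0 --out flipped.tsv
preciseadr ablate   --reports cohort.tsv --out ablation.tsv
```

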
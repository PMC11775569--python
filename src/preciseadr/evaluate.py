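"""Metrics, frequency baselines, perturbation experiments, ablations.

AUC is macro-averaged over ADRs: each evaluable ADR (at least one
positive and one negative test patient) gets a tie-corrected rank AUC
across patients, and the unweighted mean is reported. This convention
makes any scorer that is constant across patients per ADR — such as the
marginal ADR-frequency baseline — score exactly 0.5. A pooled
micro-AUC is reported alongside.

Hit@10 is the fraction of test patients (with at least one true ADR)
whose top-10 scored ADRs contain a true one; ties are broken by ADR
index. Recall@10 is provided as a secondary column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.metrics import roc_auc_score

from .cohort import AdverseEventReport, Vocabulary, build_vocabulary, split_cohort

__all__ = ["EvaluationResult", "macro_auc", "micro_auc", "hit_at_k",
           "recall_at_k", "labels_matrix", "frequency_baseline",
           "mlp_baseline", "perturb_demographics", "run_experiment",
           "ablation_harness"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvaluationResult:
    model: str
    macro_auc: float
    micro_auc: float
    hit_at_10: float
    recall_at_10: float
    per_adr_auc: dict[str, float]
    n_evaluable_adrs: int

    def to_row(self) -> dict:
        return {"model": self.model, "macro_auc": self.macro_auc,
                "micro_auc": self.micro_auc, "hit_at_10": self.hit_at_10,
                "recall_at_10": self.recall_at_10,
                "n_evaluable_adrs": self.n_evaluable_adrs}


def _evaluable(labels: np.ndarray) -> np.ndarray:
    pos = labels.sum(axis=0)
    return (pos >= 1) & (pos <= labels.shape[0] - 1)


def macro_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Unweighted mean of per-ADR tie-corrected rank AUC (Mann-Whitney
    U / (n+ n-)) over evaluable ADRs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same shape")
    cols = np.nonzero(_evaluable(labels))[0]
    if cols.size == 0:
        raise ValueError("no evaluable ADR (each needs a positive and a negative)")
    return float(np.mean([roc_auc_score(labels[:, j], scores[:, j])
                          for j in cols]))


def per_adr_auc(scores: np.ndarray, labels: np.ndarray,
                vocab: Vocabulary | None = None) -> dict:
    cols = np.nonzero(_evaluable(np.asarray(labels)))[0]
    name = (lambda j: vocab.adrs[j]) if vocab is not None else (lambda j: int(j))
    return {name(j): float(roc_auc_score(labels[:, j], scores[:, j]))
            for j in cols}


def micro_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Pooled AUC over all (patient, ADR) entries."""
    return float(roc_auc_score(np.asarray(labels).ravel(),
                               np.asarray(scores, dtype=float).ravel()))


def _top_k(scores_row: np.ndarray, k: int) -> np.ndarray:
    # stable sort on negated scores: ties resolved by lowest ADR index
    return np.argsort(-scores_row, kind="stable")[:k]


def hit_at_k(scores: np.ndarray, labels: np.ndarray, k: int = 10) -> float:
    """Fraction of patients with >= 1 true ADR among their top-k scores,
    over patients with at least one true ADR."""
    scores, labels = np.asarray(scores, dtype=float), np.asarray(labels)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > scores.shape[1]:
        raise ValueError(f"k={k} exceeds the ADR vocabulary ({scores.shape[1]})")
    hits, n = 0, 0
    for i in range(scores.shape[0]):
        if labels[i].sum() < 1:
            continue
        n += 1
        hits += bool(labels[i, _top_k(scores[i], k)].any())
    if n == 0:
        raise ValueError("no patient has a true ADR")
    return hits / n


def recall_at_k(scores: np.ndarray, labels: np.ndarray, k: int = 10) -> float:
    """Mean per-patient fraction of true ADRs recovered in the top k."""
    scores, labels = np.asarray(scores, dtype=float), np.asarray(labels)
    vals = []
    for i in range(scores.shape[0]):
        t = labels[i].sum()
        if t < 1:
            continue
        vals.append(labels[i, _top_k(scores[i], k)].sum() / t)
    return float(np.mean(vals))


def labels_matrix(reports, vocab: Vocabulary,
                  warn_unknown: bool = True) -> np.ndarray:
    """Binary patients x ADR-vocabulary matrix; ADR IDs outside the
    training vocabulary are dropped (the label space is fixed by
    training)."""
    y = np.zeros((len(reports), vocab.n_adrs))
    dropped = set()
    for i, r in enumerate(reports):
        for s in r.adrs:
            if s in vocab.adr_index:
                y[i, vocab.adr_index[s]] = 1.0
            else:
                dropped.add(s)
    if dropped and warn_unknown:
        logger.warning("%d test ADR ID(s) absent from the training vocabulary "
                       "were dropped from evaluation", len(dropped))
    return y


VARIANTS = ("random", "marginal", "given_indications", "given_drugs",
            "given_both")


def frequency_baseline(train_reports, test_reports, vocab: Vocabulary,
                       variant: str = "marginal", seed: int = 0) -> np.ndarray:
    """Frequency-based score matrices (test patients x ADR vocabulary).

    ``random``: i.i.d. Uniform(0,1). ``marginal``: the training
    frequency of each ADR, identical for every patient.
    ``given_indications`` / ``given_drugs``: the mean over the patient's
    diseases (drugs) of the Laplace-smoothed conditional P(ADR | entity)
    = (co-count + 1) / (entity count + 2). ``given_both``: the mean of
    the two conditional scores. Patients with no known entity under a
    conditional variant fall back to the marginal score.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    n_test, n_adrs = len(test_reports), vocab.n_adrs
    if variant == "random":
        return np.random.default_rng(seed).random((n_test, n_adrs))

    marginal = np.zeros(n_adrs)
    for r in train_reports:
        for s in r.adrs:
            if s in vocab.adr_index:
                marginal[vocab.adr_index[s]] += 1.0
    marginal /= max(len(train_reports), 1)
    if variant == "marginal":
        return np.tile(marginal, (n_test, 1))

    def conditional(index: dict, entities_of):
        counts = np.zeros(len(index))
        co = np.zeros((len(index), n_adrs))
        for r in train_reports:
            cols = [vocab.adr_index[s] for s in r.adrs if s in vocab.adr_index]
            for ent in entities_of(r):
                if ent in index:
                    e = index[ent]
                    counts[e] += 1.0
                    co[e, cols] += 1.0
        return (co + 1.0) / (counts[:, None] + 2.0)

    def scores_for(index, entities_of, cond):
        out = np.empty((n_test, n_adrs))
        for i, r in enumerate(test_reports):
            rows = [index[e] for e in sorted(entities_of(r)) if e in index]
            if rows:
                out[i] = cond[rows].mean(axis=0)
            else:
                logger.warning("report %s: no known entity, marginal fallback",
                               r.report_id)
                out[i] = marginal
        return out

    if variant in ("given_indications", "given_both"):
        cond_d = conditional(vocab.disease_index, lambda r: r.diseases)
        s_ind = scores_for(vocab.disease_index, lambda r: r.diseases, cond_d)
        if variant == "given_indications":
            return s_ind
    cond_m = conditional(vocab.drug_index, lambda r: r.drugs)
    s_drug = scores_for(vocab.drug_index, lambda r: r.drugs, cond_m)
    if variant == "given_drugs":
        return s_drug
    return 0.5 * (s_ind + s_drug)


def mlp_baseline(train_reports, test_reports, vocab: Vocabulary,
                 hidden: int = 64, epochs: int = 150, lr: float = 1e-2,
                 gamma: float = 2.0, seed: int = 0) -> EvaluationResult:
    """The drug-only reference point: a two-layer perceptron on the drug
    multi-hot block alone (no diseases, no demographics), trained with
    focal BCE. See :class:`preciseadr.estimators.DrugOnlyMLP`."""
    from .estimators import DrugOnlyMLP
    model = DrugOnlyMLP(hidden=hidden, epochs=epochs, lr=lr, gamma=gamma,
                        random_state=seed)
    model.fit(train_reports, vocab=vocab)
    scores = model.predict_proba(test_reports)
    labels = labels_matrix(test_reports, vocab)
    return evaluation_result("mlp_drug_only", scores, labels, vocab)


def evaluation_result(name: str, scores: np.ndarray, labels: np.ndarray,
                      vocab: Vocabulary | None = None) -> EvaluationResult:
    k = min(10, scores.shape[1])
    return EvaluationResult(
        model=name,
        macro_auc=macro_auc(scores, labels),
        micro_auc=micro_auc(scores, labels),
        hit_at_10=hit_at_k(scores, labels, k),
        recall_at_10=recall_at_k(scores, labels, k),
        per_adr_auc=per_adr_auc(scores, labels, vocab),
        n_evaluable_adrs=int(_evaluable(np.asarray(labels)).sum()),
    )


def perturb_demographics(test_reports, mode: str = "gender",
                         seed: int = 0) -> list[AdverseEventReport]:
    """Demographic perturbation of a test cohort.

    ``gender`` flips every sex code 1<->2 (an involution); ``age``
    permutes ages uniformly across patients (preserving the age
    multiset); ``both`` applies both. Diseases, drugs and labels are
    untouched.
    """
    if mode not in ("gender", "age", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    reports = list(test_reports)
    out = []
    ages = [r.age for r in reports]
    if mode in ("age", "both"):
        perm = np.random.default_rng(seed).permutation(len(reports))
        ages = [reports[j].age for j in perm]
    for r, a in zip(reports, ages):
        sex = r.sex
        if mode in ("gender", "both") and sex is not None:
            sex = 3 - sex
        out.append(replace(r, sex=sex, age=a))
    return out


def run_experiment(reports, model, seed: int = 0,
                   fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                   train_fraction: float = 1.0,
                   perturb: str | None = None,
                   adr_subset: list[str] | None = None,
                   baselines: tuple[str, ...] = (),
                   ) -> dict[str, EvaluationResult]:
    """Split a cohort, fit the model, score the held-out patients.

    ``model`` is any estimator with ``fit(train_reports, vocab=...,
    val_reports=...)`` and ``predict_proba(test_reports)``.
    ``train_fraction`` subsamples the training split (ablation);
    ``perturb`` applies a demographic perturbation to the test reports
    before scoring; ``adr_subset`` restricts metrics to those ADR
    columns; ``baselines`` adds frequency-baseline results.
    """
    train, val, test = split_cohort(reports, fractions, seed)
    if train_fraction < 1.0:
        keep = np.random.default_rng(seed + 1).choice(
            len(train), size=max(2, int(round(train_fraction * len(train)))),
            replace=False)
        train = [train[i] for i in keep]
    vocab = build_vocabulary(train)
    test_in = perturb_demographics(test, perturb, seed) if perturb else test
    labels = labels_matrix(test, vocab)

    cols = None
    if adr_subset is not None:
        cols = [vocab.adr_index[s] for s in adr_subset if s in vocab.adr_index]

    def restricted(scores, labels):
        if cols is None:
            return scores, labels
        return scores[:, cols], labels[:, cols]

    model.fit(train, vocab=vocab, val_reports=val)
    scores = model.predict_proba(test_in)
    name = getattr(model, "name", type(model).__name__)
    results = {name: evaluation_result(name, *restricted(scores, labels))}
    for variant in baselines:
        s = frequency_baseline(train, test_in, vocab, variant, seed)
        results[variant] = evaluation_result(variant, *restricted(s, labels))
    return results


def ablation_harness(reports, model_factory, fractions_grid=(0.25, 0.5, 1.0),
                     alpha_grid=(0.1,), seeds=(0, 1, 2)) -> pd.DataFrame:
    """Long-format results over (training fraction, alpha, seed).

    ``model_factory(alpha, seed)`` must return a fresh estimator. The
    Spearman correlation between training fraction and macro-AUC is a
    reported statistic (see :func:`training_size_spearman`), never an
    assertion.
    """
    rows = []
    for frac in fractions_grid:
        for alpha in alpha_grid:
            for seed in seeds:
                model = model_factory(alpha, seed)
                res = run_experiment(reports, model, seed=seed,
                                     train_fraction=frac)
                r = next(iter(res.values()))
                rows.append({"train_fraction": frac, "alpha": alpha,
                             "seed": seed, **r.to_row()})
    return pd.DataFrame(rows)


def training_size_spearman(table: pd.DataFrame) -> float:
    """Spearman rank correlation between training fraction and macro-AUC."""
    rho, _ = spearmanr(table["train_fraction"], table["macro_auc"])
    return float(rho)
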
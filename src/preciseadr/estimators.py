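"""Scikit-learn style estimators for patient-level ADR prediction.

``X`` is a list of :class:`~preciseadr.cohort.AdverseEventReport`; the
multi-label target is carried by each report's ``adrs`` field, so ``y``
is never passed separately. All estimators follow the fit /
predict_proba contract with ``get_params``/``set_params`` and
trailing-underscore fitted attributes, and compose with sklearn
model-selection utilities.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from ._autodiff import Adam, Tensor
from .cohort import Vocabulary, build_vocabulary
from .graph import FeatureConfig, attach_patients, build_graph
from .hgt import HGTConfig
from .training import (AugmentConfig, LossConfig, TrainConfig, focal_loss,
                       forward, train)
from .evaluate import frequency_baseline, labels_matrix

__all__ = ["PreciseADR", "FrequencyBaseline", "DrugOnlyMLP"]

logger = logging.getLogger(__name__)


def _check_fitted(est, attr: str) -> None:
    if not hasattr(est, attr):
        raise NotFittedError(f"{type(est).__name__} is not fitted yet")


class PreciseADR(BaseEstimator):
    """Heterogeneous-graph-transformer ADR predictor.

    Fitting builds the AER graph from the training reports (plus an
    optional validation set attached inductively for early stopping) and
    optimizes the combined focal + InfoNCE objective with full-batch
    Adam. Prediction attaches new patients to the trained graph by their
    diseases and drugs and scores all ADRs in the training vocabulary.

    Parameters mirror the architecture and objective: ``d``/``h``/``L``
    the encoder width, heads and depth; ``epsilon``/``noise_scale`` the
    augmentation; ``gamma`` the focal focusing parameter; ``alpha`` the
    InfoNCE weight (0 disables the contrastive branch).
    """

    name = "preciseadr"

    def __init__(self, d: int = 64, h: int = 4, L: int = 2,
                 epsilon: float = 0.5, noise_scale: float = 0.1,
                 gamma: float = 2.0, alpha: float = 0.1,
                 temperature: float = 1.0, batch_size: int = 256,
                 lr: float = 1e-3, weight_decay: float = 0.0,
                 max_epochs: int = 200, patience: int = 20,
                 eval_every: int = 1, include_demographics: bool = True,
                 random_state: int = 0):
        self.d = d
        self.h = h
        self.L = L
        self.epsilon = epsilon
        self.noise_scale = noise_scale
        self.gamma = gamma
        self.alpha = alpha
        self.temperature = temperature
        self.batch_size = batch_size
        self.lr = lr
        self.weight_decay = weight_decay
        self.max_epochs = max_epochs
        self.patience = patience
        self.eval_every = eval_every
        self.include_demographics = include_demographics
        self.random_state = random_state

    def _configs(self):
        return (HGTConfig(d=self.d, h=self.h, L=self.L),
                AugmentConfig(epsilon=self.epsilon,
                              noise_scale=self.noise_scale),
                LossConfig(gamma=self.gamma, alpha=self.alpha,
                           temperature=self.temperature,
                           batch_size=self.batch_size),
                TrainConfig(lr=self.lr, weight_decay=self.weight_decay,
                            max_epochs=self.max_epochs,
                            patience=self.patience,
                            eval_every=self.eval_every,
                            seed=self.random_state))

    def fit(self, X, y=None, vocab: Vocabulary | None = None,
            val_reports=None):
        reports = list(X)
        self.vocab_ = vocab if vocab is not None else build_vocabulary(reports)
        fc = FeatureConfig(include_demographics=self.include_demographics)
        self.graph_ = build_graph(reports, self.vocab_, fc)
        hgt_cfg, aug_cfg, loss_cfg, train_cfg = self._configs()
        validation = None
        if val_reports:
            val_reports = list(val_reports)
            val_graph = attach_patients(self.graph_, val_reports)
            rows = np.arange(self.graph_.n_patients, val_graph.n_patients)
            validation = (val_graph, rows,
                          labels_matrix(val_reports, self.vocab_))
        self.params_, self.head_, history = train(
            self.graph_, hgt_cfg, aug_cfg, loss_cfg, train_cfg, validation)
        self.history_ = history
        self.classes_ = np.array(self.vocab_.adrs)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-ADR probabilities, shape (n_reports, n_adrs)."""
        _check_fitted(self, "params_")
        reports = list(X)
        g = attach_patients(self.graph_, reports)
        hgt_cfg, aug_cfg, _, _ = self._configs()
        _, _, y_prob = forward(g, self.params_, self.head_, hgt_cfg, aug_cfg,
                               mode="eval")
        return y_prob.data[self.graph_.n_patients:]

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


class FrequencyBaseline(BaseEstimator):
    """ADR-frequency scoring baselines.

    ``variant`` one of ``random`` (uniform scores), ``marginal``
    (training ADR frequency, constant across patients — macro-AUC is
    exactly 0.5 by construction), ``given_indications``, ``given_drugs``
    and ``given_both`` (Laplace-smoothed conditional frequencies
    averaged over the patient's diseases and/or drugs).
    """

    def __init__(self, variant: str = "marginal", random_state: int = 0):
        self.variant = variant
        self.random_state = random_state

    @property
    def name(self) -> str:
        return f"freq_{self.variant}"

    def fit(self, X, y=None, vocab: Vocabulary | None = None,
            val_reports=None):
        self.train_reports_ = list(X)
        self.vocab_ = vocab if vocab is not None else build_vocabulary(
            self.train_reports_)
        self.classes_ = np.array(self.vocab_.adrs)
        return self

    def predict_proba(self, X) -> np.ndarray:
        _check_fitted(self, "vocab_")
        return frequency_baseline(self.train_reports_, list(X), self.vocab_,
                                  self.variant, self.random_state)


class DrugOnlyMLP(BaseEstimator):
    """Two-layer perceptron on the drug multi-hot block only.

    The drug-level reference point: no disease and no demographic
    inputs, trained with the same focal BCE as the main model. Useful
    for showing what patient context adds — on cohorts whose ADRs are
    driven purely by demographics this model cannot beat chance.
    """

    name = "mlp_drug_only"

    def __init__(self, hidden: int = 64, epochs: int = 150, lr: float = 1e-2,
                 gamma: float = 2.0, random_state: int = 0):
        self.hidden = hidden
        self.epochs = epochs
        self.lr = lr
        self.gamma = gamma
        self.random_state = random_state

    def _features(self, reports, inductive: bool) -> np.ndarray:
        x = np.zeros((len(reports), self.vocab_.n_drugs))
        for i, r in enumerate(reports):
            for m in r.drugs:
                if m in self.vocab_.drug_index:
                    x[i, self.vocab_.drug_index[m]] = 1.0
                elif inductive:
                    logger.warning("drug %s unseen in training, dropped", m)
                else:
                    raise KeyError(f"unknown drug {m}")
        return x

    def fit(self, X, y=None, vocab: Vocabulary | None = None,
            val_reports=None):
        reports = list(X)
        self.vocab_ = vocab if vocab is not None else build_vocabulary(reports)
        x = self._features(reports, inductive=False)
        yb = labels_matrix(reports, self.vocab_, warn_unknown=False)
        rng = np.random.default_rng(self.random_state)

        def xavier(shape):
            b = np.sqrt(6.0 / sum(shape))
            return rng.uniform(-b, b, size=shape)
        w1 = Tensor(xavier((x.shape[1], self.hidden)), requires_grad=True)
        b1 = Tensor(np.zeros(self.hidden), requires_grad=True)
        w2 = Tensor(xavier((self.hidden, self.vocab_.n_adrs)),
                    requires_grad=True)
        b2 = Tensor(np.zeros(self.vocab_.n_adrs), requires_grad=True)
        opt = Adam([w1, b1, w2, b2], lr=self.lr)
        xt = Tensor(x)
        for _ in range(self.epochs):
            prob = ((xt @ w1 + b1).relu() @ w2 + b2).sigmoid()
            loss = focal_loss(prob, yb, self.gamma)
            opt.zero_grad()
            loss.backward()
            opt.step()
        self.weights_ = (w1.data, b1.data, w2.data, b2.data)
        self.classes_ = np.array(self.vocab_.adrs)
        return self

    def predict_proba(self, X) -> np.ndarray:
        _check_fitted(self, "weights_")
        w1, b1, w2, b2 = self.weights_
        x = self._features(list(X), inductive=True)
        hidden = np.maximum(x @ w1 + b1, 0.0)
        z = hidden @ w2 + b2
        return 0.5 * (1.0 + np.tanh(0.5 * z))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)
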
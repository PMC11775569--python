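"""Augmentation branch, predictor head, losses, and the training loop.

Two views of every patient are produced: the graph view ``H_P^L`` from
the HGT encoder, and the augmentation view ``H_P^S`` from a single
fully-connected layer applied to noise-augmented patient features,

    Aug(X) = X + (E - Dropout(E, eps)),   E ~ N(0, sigma^2) i.i.d.

(dropout zeroes entries with probability eps and rescales survivors by
1/(1-eps); at evaluation time Aug is the identity). The predictor is a
sigmoid FC layer on the sum of the two views, giving independent
per-ADR probabilities (multi-label, not softmax-normalized).

The objective mixes a multi-label focal binary cross-entropy (focusing
parameter gamma) with an InfoNCE term that treats the two views of the
same patient as the positive pair within a batch:

    L = alpha * L_infonce + (1 - alpha) * L_focal
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._autodiff import Adam, Tensor, take_rows
from .graph import AERGraph
from .hgt import HGTConfig, encode, init_hgt_params

__all__ = ["AugmentConfig", "LossConfig", "TrainConfig", "augment",
           "augment_encode", "predict", "focal_loss", "infonce_loss",
           "total_loss", "init_head_params", "forward", "train"]

logger = logging.getLogger(__name__)

PROB_EPS = 1e-7


@dataclass(frozen=True)
class AugmentConfig:
    """Noise-augmentation knobs: dropout rate eps and noise std sigma."""

    epsilon: float = 0.5
    noise_scale: float = 0.1
    enabled_at_eval: bool = False

    def __post_init__(self):
        if not 0.0 <= self.epsilon < 1.0:
            raise ValueError("epsilon must be in [0, 1)")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")


@dataclass(frozen=True)
class LossConfig:
    gamma: float = 2.0        # focal focusing parameter
    alpha: float = 0.1        # InfoNCE mixing weight
    temperature: float = 1.0  # cosine-similarity temperature
    batch_size: int = 256     # InfoNCE batch B

    def __post_init__(self):
        if self.gamma < 0 or not 0.0 <= self.alpha <= 1.0:
            raise ValueError("require gamma >= 0 and alpha in [0, 1]")


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    weight_decay: float = 0.0
    max_epochs: int = 200
    patience: int = 20        # early-stopping patience, in evaluations
    eval_every: int = 1       # epochs between validation evaluations
    ema_decay: float = 0.0    # >0 enables Polyak-averaged evaluation weights
    lr_plateau_factor: float = 0.5   # lr multiplier after patience/2 stalls
    seed: int = 0


def augment(x: np.ndarray, cfg: AugmentConfig, mode: str = "train",
            rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Aug(X) = X + (E - Dropout(E, eps)) in train mode; identity at eval."""
    if mode not in ("train", "eval"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "eval" and not cfg.enabled_at_eval:
        return np.array(x, copy=True)
    if cfg.noise_scale == 0.0 or cfg.epsilon == 0.0:
        # Dropout(E, 0) = E, so the perturbation vanishes identically
        return np.array(x, copy=True)
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    e = rng.normal(0.0, cfg.noise_scale, size=np.shape(x))
    keep = rng.random(np.shape(x)) >= cfg.epsilon
    dropped = e * keep / (1.0 - cfg.epsilon)
    return np.asarray(x) + (e - dropped)


def init_head_params(feature_dim: int, d: int, n_adrs: int,
                     seed: int = 0) -> dict[str, Tensor]:
    """Augmentation FC (feature_dim -> d) and predictor FC (d -> n_adrs)."""
    rng = np.random.default_rng(seed)

    def xavier(shape):
        bound = np.sqrt(6.0 / (shape[0] + shape[1]))
        return rng.uniform(-bound, bound, size=shape)
    return {
        "W_aug": Tensor(xavier((feature_dim, d)), requires_grad=True),
        "b_aug": Tensor(np.zeros(d), requires_grad=True),
        "W_pred": Tensor(xavier((d, n_adrs)), requires_grad=True),
        "b_pred": Tensor(np.zeros(n_adrs), requires_grad=True),
    }


def augment_encode(x_aug: Tensor | np.ndarray, head: dict[str, Tensor]) -> Tensor:
    """H_P^S: one affine map to width d plus GELU."""
    x_aug = x_aug if isinstance(x_aug, Tensor) else Tensor(x_aug)
    if x_aug.shape[-1] != head["W_aug"].shape[0]:
        raise ValueError(f"feature width {x_aug.shape[-1]} does not match "
                         f"augmentation input {head['W_aug'].shape[0]}")
    return (x_aug @ head["W_aug"] + head["b_aug"]).gelu()


def predict(h_graph: Tensor | np.ndarray, h_aug: Tensor | np.ndarray,
            head: dict[str, Tensor]) -> Tensor:
    """Ỹ = sigmoid(FC(H_P^L + H_P^S)): per-ADR probabilities in (0, 1)."""
    h_graph = h_graph if isinstance(h_graph, Tensor) else Tensor(h_graph)
    h_aug = h_aug if isinstance(h_aug, Tensor) else Tensor(h_aug)
    if h_graph.shape[0] != h_aug.shape[0]:
        raise ValueError("the two patient views have different row counts")
    return ((h_graph + h_aug) @ head["W_pred"] + head["b_pred"]).sigmoid()


def focal_loss(y_prob: Tensor | np.ndarray, y: np.ndarray,
               gamma: float = 2.0) -> Tensor:
    """Multi-label focal binary cross-entropy, averaged over all entries:

        -[ Y (1-p)^g log p + (1-Y) p^g log(1-p) ]

    which reduces to plain BCE at gamma = 0. Probabilities are clamped
    to [1e-7, 1 - 1e-7].
    """
    y_prob = y_prob if isinstance(y_prob, Tensor) else Tensor(y_prob)
    y = np.asarray(y, dtype=np.float64)
    if y_prob.shape != y.shape:
        raise ValueError(f"shape mismatch {y_prob.shape} vs {y.shape}")
    p = y_prob.clip(PROB_EPS, 1.0 - PROB_EPS)
    pos = Tensor(y) * ((1.0 - p) ** gamma) * p.log()
    neg = Tensor(1.0 - y) * (p ** gamma) * (1.0 - p).log()
    return -(pos + neg).mean()


def _row_normalize(h: Tensor) -> Tensor:
    # zero-norm rows map to zero vectors (cosine similarity 0 by convention)
    norm_sq = (h * h).sum(axis=1, keepdims=True)
    if np.any(norm_sq.data < 1e-24):
        logger.warning("zero-norm row(s) in InfoNCE batch; similarity set to 0")
    return h * ((norm_sq + 1e-24) ** -0.5)


def infonce_loss(h_graph: Tensor | np.ndarray, h_aug: Tensor | np.ndarray,
                 temperature: float = 1.0) -> Tensor:
    """InfoNCE over a batch of B patients with cosine similarity:

        -(1/B) sum_i log( exp(sim_ii/T) / sum_j exp(sim_ij/T) )

    where row i of the graph view is the anchor and the augmentation
    views are the candidates; the matching patient is the positive.
    """
    h_graph = h_graph if isinstance(h_graph, Tensor) else Tensor(h_graph)
    h_aug = h_aug if isinstance(h_aug, Tensor) else Tensor(h_aug)
    if h_graph.shape != h_aug.shape:
        raise ValueError("view shapes differ")
    b = h_graph.shape[0]
    sim = _row_normalize(h_graph) @ _transpose(_row_normalize(h_aug))
    sim = sim * (1.0 / temperature)
    row_max = Tensor(sim.data.max(axis=1, keepdims=True))   # constant shift
    e = (sim - row_max).exp()
    log_denom = e.sum(axis=1, keepdims=True).log() + row_max
    eye = np.eye(b)
    diag = (sim * eye).sum(axis=1, keepdims=True)
    return (log_denom - diag).mean()


def _transpose(t: Tensor) -> Tensor:
    def back(g):
        t._accumulate(g.T)
    return Tensor(t.data.T, parents=(t,), backward=back)


def total_loss(focal: Tensor | float, infonce: Tensor | float,
               alpha: float) -> Tensor:
    """L = alpha * L_infonce + (1 - alpha) * L_focal."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    focal = focal if isinstance(focal, Tensor) else Tensor(focal)
    infonce = infonce if isinstance(infonce, Tensor) else Tensor(infonce)
    return alpha * infonce + (1.0 - alpha) * focal


def forward(graph: AERGraph, params: dict[str, Tensor],
            head: dict[str, Tensor], hgt_config: HGTConfig,
            aug_config: AugmentConfig, mode: str = "eval",
            rng: np.random.Generator | None = None
            ) -> tuple[Tensor, Tensor, Tensor]:
    """Full model pass: returns (H_P^L, H_P^S, Ỹ) over all patients."""
    h = encode(graph, params, hgt_config)
    x_aug = augment(graph.x_patient, aug_config, mode, rng)
    h_aug = augment_encode(x_aug, head)
    h_graph = h["patient"]
    return h_graph, h_aug, predict(h_graph, h_aug, head)


def train(graph: AERGraph,
          hgt_config: HGTConfig = HGTConfig(),
          aug_config: AugmentConfig = AugmentConfig(),
          loss_config: LossConfig = LossConfig(),
          train_config: TrainConfig = TrainConfig(),
          validation: tuple[AERGraph, np.ndarray, np.ndarray] | None = None,
          metric_fn=None,
          ) -> tuple[dict[str, Tensor], dict[str, Tensor], list[dict]]:
    """Full-batch Adam training with early stopping.

    ``validation``, when given, is ``(graph_with_val_attached, val_rows,
    val_labels)``: every ``eval_every`` epochs the model scores the
    attached validation patients and ``metric_fn(scores, labels)``
    (macro-AUC by default) drives early stopping with the configured
    patience; the best parameters are restored at the end. Returns
    (encoder params, head params, per-epoch history).
    """
    if metric_fn is None:
        from .evaluate import macro_auc
        metric_fn = macro_auc
    rng = np.random.default_rng(train_config.seed)
    feature_dims = {t: graph.node_features(t).shape[1]
                    for t in hgt_config.node_types}
    params = init_hgt_params(hgt_config, feature_dims, seed=train_config.seed)
    head = init_head_params(graph.x_patient.shape[1], hgt_config.d,
                            graph.vocab.n_adrs, seed=train_config.seed + 1)
    # prior-probability bias init: start each ADR at its training prevalence
    # (the standard focal-loss recipe for rare positives)
    prior = np.clip(graph.y.mean(axis=0), PROB_EPS, 1 - PROB_EPS)
    head["b_pred"].data = np.log(prior / (1 - prior))
    trainable = list(params.values()) + list(head.values())
    opt = Adam(trainable, lr=train_config.lr,
               weight_decay=train_config.weight_decay)
    use_ema = train_config.ema_decay > 0
    ema = [p.data.copy() for p in trainable] if use_ema else None

    def eval_weights():
        return ema if use_ema else [p.data for p in trainable]

    def with_eval_weights(fn):
        if not use_ema:
            return fn()
        saved = [p.data for p in trainable]
        for p, e in zip(trainable, ema):
            p.data = e
        try:
            return fn()
        finally:
            for p, s in zip(trainable, saved):
                p.data = s

    n_train = graph.n_train_patients
    history: list[dict] = []
    best_metric, best_state, strikes = -np.inf, None, 0

    for epoch in range(1, train_config.max_epochs + 1):
        h_graph, h_aug, y_prob = forward(graph, params, head, hgt_config,
                                         aug_config, mode="train", rng=rng)
        train_rows = np.arange(n_train)
        l_focal = focal_loss(take_rows(y_prob, train_rows), graph.y,
                             loss_config.gamma)
        if loss_config.alpha > 0:
            b = min(loss_config.batch_size, n_train)
            batch = rng.choice(n_train, size=b, replace=False)
            l_nce = infonce_loss(take_rows(h_graph, batch),
                                 take_rows(h_aug, batch),
                                 loss_config.temperature)
        else:
            l_nce = Tensor(0.0)
        loss = total_loss(l_focal, l_nce, loss_config.alpha)
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        if use_ema:
            for e, p in zip(ema, trainable):
                e *= train_config.ema_decay
                e += (1 - train_config.ema_decay) * p.data

        entry = {"epoch": epoch, "focal": float(l_focal.data),
                 "infonce": float(l_nce.data), "total": float(loss.data),
                 "val_metric": np.nan}
        if validation is not None and epoch % train_config.eval_every == 0:
            val_graph, val_rows, val_labels = validation
            val_prob = with_eval_weights(lambda: forward(
                val_graph, params, head, hgt_config, aug_config,
                mode="eval")[2])
            metric = metric_fn(val_prob.data[val_rows], val_labels)
            entry["val_metric"] = float(metric)
            if metric > best_metric:
                best_metric, strikes = metric, 0
                best_state = [w.copy() for w in eval_weights()]
            else:
                strikes += 1
                if strikes == max(1, train_config.patience // 2):
                    opt.lr *= train_config.lr_plateau_factor
            if strikes >= train_config.patience:
                history.append(entry)
                logger.info("early stop at epoch %d (best val %.4f)",
                            epoch, best_metric)
                break
        history.append(entry)

    final = best_state if best_state is not None else eval_weights()
    for p, d in zip(trainable, final):
        p.data = d.copy()
    return params, head, history
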
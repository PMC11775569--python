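"""Heterogeneous graph transformer (HGT) encoder for the AER graph.

Each layer computes, per directed edge (s, e, t) and attention head i,

    ATT_i(s,e,t) = (K_i(s) W^ATT_phi(e) Q_i(t)^T) * mu_<tau(s),phi(e),tau(t)>
                   / sqrt(d_h)
    MSG_i(s,e,t) = (M-Linear_tau(s),i H[s]) W^MSG_phi(e)

with K/Q/M projections specific to the node type and W^ATT/W^MSG to the
edge type. Attention is softmax-normalized over ALL incoming edges of
each target node, jointly across edge types, per head. The aggregate is
the attention-weighted sum of messages, passed through a target-type
output projection and GELU, added residually:

    H'[t] = H[t] + GELU(A-Linear_tau(t)(sum_e ATT(e) * MSG(e)))

Nodes with no incoming edges keep their representation unchanged.

The attention-logit divisor is sqrt(d_h) (per-head width), the
conventional transformer scaling; a literal divisor of d is available
via ``HGTConfig.attention_scale = "d"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._autodiff import (Tensor, concat, head_linear, layer_norm,
                        segment_softmax, segment_sum, take_rows)
from .graph import AERGraph, EDGE_TYPES, NODE_TYPES

__all__ = ["HGTConfig", "init_hgt_params", "project_input",
           "compute_attention", "compute_message", "hgt_layer", "encode"]


@dataclass(frozen=True)
class HGTConfig:
    """Architecture of the encoder.

    ``d`` hidden width, ``h`` attention heads (must divide ``d``),
    ``L`` layers. The meta-relation list defaults to the AER graph's
    four directed edge types.
    """

    d: int = 64
    h: int = 4
    L: int = 2
    node_types: tuple[str, ...] = NODE_TYPES
    edge_types: tuple[str, ...] = tuple(EDGE_TYPES)
    activation: str = "gelu"
    residual: bool = True
    attention_scale: str = "sqrt_dh"   # or "d" (the literal printed form)

    def __post_init__(self):
        if self.d % self.h != 0:
            raise ValueError(f"heads ({self.h}) must divide width ({self.d})")
        if self.L < 1:
            raise ValueError("at least one layer is required")
        unknown = set(self.edge_types) - set(EDGE_TYPES)
        if unknown:
            raise ValueError(f"unknown edge types {sorted(unknown)}")

    @property
    def d_h(self) -> int:
        return self.d // self.h

    @property
    def att_denominator(self) -> float:
        return math.sqrt(self.d_h) if self.attention_scale == "sqrt_dh" else float(self.d)


def _activation(x: Tensor, name: str) -> Tensor:
    if name == "gelu":
        return x.gelu()
    if name == "relu":
        return x.relu()
    if name == "tanh":
        return x.tanh()
    raise ValueError(f"unknown activation {name!r}")


def _xavier(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[-2], shape[-1]
    bound = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


def init_hgt_params(config: HGTConfig, feature_dims: dict[str, int],
                    seed: int = 0) -> dict[str, Tensor]:
    """All trainable tensors of the encoder, Xavier-initialized, mu = 1.

    Keys: ``W_<type>``, ``ln_gamma_<type>``, ``ln_beta_<type>`` for the
    input projection; per layer l: ``{K,Q,M,A}_<l>_<type>``,
    ``Ab_<l>_<type>`` (output bias), ``Watt_<l>_<edge>``,
    ``Wmsg_<l>_<edge>``, ``mu_<l>_<edge>``.
    """
    rng = np.random.default_rng(seed)
    p: dict[str, Tensor] = {}
    for t in config.node_types:
        p[f"W_{t}"] = Tensor(_xavier(rng, (feature_dims[t], config.d)),
                             requires_grad=True)
        p[f"ln_gamma_{t}"] = Tensor(np.ones(config.d), requires_grad=True)
        p[f"ln_beta_{t}"] = Tensor(np.zeros(config.d), requires_grad=True)
    for l in range(config.L):
        for t in config.node_types:
            for name in ("K", "Q", "M", "A"):
                p[f"{name}_{l}_{t}"] = Tensor(_xavier(rng, (config.d, config.d)),
                                              requires_grad=True)
            p[f"Ab_{l}_{t}"] = Tensor(np.zeros(config.d), requires_grad=True)
        for e in config.edge_types:
            p[f"Watt_{l}_{e}"] = Tensor(
                _xavier(rng, (config.h, config.d_h, config.d_h)),
                requires_grad=True)
            p[f"Wmsg_{l}_{e}"] = Tensor(
                _xavier(rng, (config.h, config.d_h, config.d_h)),
                requires_grad=True)
            p[f"mu_{l}_{e}"] = Tensor(np.ones(config.h), requires_grad=True)
    return p


def project_input(features: dict[str, Tensor | np.ndarray],
                  params: dict[str, Tensor],
                  config: HGTConfig) -> dict[str, Tensor]:
    """H^1_T = LayerNorm(X_T W_T) per node type."""
    out = {}
    for t, x in features.items():
        x = x if isinstance(x, Tensor) else Tensor(x)
        w = params[f"W_{t}"]
        if x.shape[-1] != w.shape[0]:
            raise ValueError(f"feature width {x.shape[-1]} of type {t!r} does "
                             f"not match projection input {w.shape[0]}")
        out[t] = layer_norm(x @ w, params[f"ln_gamma_{t}"], params[f"ln_beta_{t}"])
    return out


def _incoming(graph: AERGraph, config: HGTConfig, target_type: str):
    """Edge types of the config that point at `target_type`, with arrays."""
    for name in config.edge_types:
        src_t, dst_t = EDGE_TYPES[name]
        if dst_t == target_type and graph.edges[name].shape[1] > 0:
            yield name, src_t, graph.edges[name]


def _attention_scores(h: dict[str, Tensor], graph: AERGraph,
                      params: dict[str, Tensor], config: HGTConfig, layer: int,
                      target_type: str):
    """Per incoming edge type: raw logits (E, heads) and source/target ids."""
    pieces = []
    for name, src_t, e in _incoming(graph, config, target_type):
        k = (h[src_t] @ params[f"K_{layer}_{src_t}"]
             ).reshape(-1, config.h, config.d_h)
        q = (h[target_type] @ params[f"Q_{layer}_{target_type}"]
             ).reshape(-1, config.h, config.d_h)
        kw = head_linear(take_rows(k, e[0]), params[f"Watt_{layer}_{name}"])
        logits = (kw * take_rows(q, e[1])).sum(axis=-1)       # (E, h)
        logits = logits * (params[f"mu_{layer}_{name}"]
                           * (1.0 / config.att_denominator))
        pieces.append((name, logits, e))
    return pieces


def compute_attention(h: dict[str, Tensor | np.ndarray], graph: AERGraph,
                      params: dict[str, Tensor], config: HGTConfig,
                      layer: int = 0) -> dict[str, np.ndarray]:
    """Softmax-normalized attention weights per edge type, shape (E, heads).

    Normalization runs over all incoming edges of each target node,
    jointly across edge types; weights for each (target, head) with
    in-degree > 0 sum to one.
    """
    h = {t: (x if isinstance(x, Tensor) else Tensor(x)) for t, x in h.items()}
    out: dict[str, np.ndarray] = {}
    for t in config.node_types:
        pieces = _attention_scores(h, graph, params, config, layer, t)
        if not pieces:
            continue
        logits = concat([p[1] for p in pieces], axis=0)
        seg = np.concatenate([p[2][1] for p in pieces])
        att = segment_softmax(logits, seg, graph.n_nodes(t))
        offset = 0
        for name, piece_logits, e in pieces:
            n = piece_logits.shape[0]
            out[name] = att.data[offset:offset + n]
            offset += n
    return out


def compute_message(h: dict[str, Tensor | np.ndarray], graph: AERGraph,
                    params: dict[str, Tensor], config: HGTConfig,
                    layer: int = 0) -> dict[str, np.ndarray]:
    """Per-edge messages with heads concatenated to width d."""
    h = {t: (x if isinstance(x, Tensor) else Tensor(x)) for t, x in h.items()}
    out = {}
    for name in config.edge_types:
        src_t, _ = EDGE_TYPES[name]
        e = graph.edges[name]
        if e.shape[1] == 0:
            out[name] = np.empty((0, config.d))
            continue
        m = (h[src_t] @ params[f"M_{layer}_{src_t}"]
             ).reshape(-1, config.h, config.d_h)
        msg = head_linear(take_rows(m, e[0]), params[f"Wmsg_{layer}_{name}"])
        out[name] = msg.data.reshape(-1, config.d)
    return out


def hgt_layer(h: dict[str, Tensor], graph: AERGraph,
              params: dict[str, Tensor], config: HGTConfig,
              layer: int) -> dict[str, Tensor]:
    """One attention/message/aggregate pass over every node type."""
    out: dict[str, Tensor] = {}
    for t in config.node_types:
        pieces = _attention_scores(h, graph, params, config, layer, t)
        if not pieces:
            out[t] = h[t]
            continue
        n_t = graph.n_nodes(t)
        logits = concat([p[1] for p in pieces], axis=0)
        seg = np.concatenate([p[2][1] for p in pieces])
        att = segment_softmax(logits, seg, n_t)               # (E_total, h)

        msgs = []
        for name, _, e in pieces:
            src_t = EDGE_TYPES[name][0]
            m = (h[src_t] @ params[f"M_{layer}_{src_t}"]
                 ).reshape(-1, config.h, config.d_h)
            msgs.append(head_linear(take_rows(m, e[0]),
                                    params[f"Wmsg_{layer}_{name}"]))
        msg = concat(msgs, axis=0)                            # (E_total, h, d_h)
        weighted = msg * att.reshape(-1, config.h, 1)
        agg = segment_sum(weighted, seg, n_t).reshape(n_t, config.d)

        upd = _activation(agg @ params[f"A_{layer}_{t}"] + params[f"Ab_{layer}_{t}"],
                          config.activation)
        # isolated targets keep their representation exactly
        indeg = np.zeros((n_t, 1))
        np.add.at(indeg, seg, 1.0)
        upd = upd * Tensor(indeg > 0)
        out[t] = (h[t] + upd) if config.residual else upd
    return out


def encode(graph: AERGraph, params: dict[str, Tensor], config: HGTConfig,
           patient_features: Tensor | np.ndarray | None = None
           ) -> dict[str, Tensor]:
    """Project inputs and apply L layers; returns per-type representations.

    ``patient_features`` overrides the graph's stored patient matrix
    (used for the perturbation experiments). Raises on non-finite
    values, naming the layer.
    """
    feats = {t: graph.node_features(t) for t in config.node_types}
    if patient_features is not None:
        feats["patient"] = patient_features
    h = project_input(feats, params, config)
    for l in range(config.L):
        h = hgt_layer(h, graph, params, config, l)
        for t, x in h.items():
            if not np.isfinite(x.data).all():
                raise FloatingPointError(
                    f"non-finite representation for type {t!r} after layer {l}")
    return h
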
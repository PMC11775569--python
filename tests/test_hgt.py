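"""Encoder correctness against a brute-force dense oracle.

The oracle re-implements projection, attention, messages and
aggregation with explicit Python loops over nodes, edges and heads —
no shared code with the package's vectorized path.
"""

import math

import numpy as np
import pytest
from scipy.special import erf

from preciseadr._autodiff import Tensor
from preciseadr.cohort import build_vocabulary
from preciseadr.graph import EDGE_TYPES, FeatureConfig, build_graph
from preciseadr.hgt import (HGTConfig, compute_attention, compute_message,
                            encode, hgt_layer, init_hgt_params, project_input)
from .conftest import make_report


def toy_graph(n_reports=4, seed=0, n_dis=3, n_drug=3):
    rng = np.random.default_rng(seed)
    reports = []
    for i in range(n_reports):
        dis = rng.choice(n_dis, size=rng.integers(1, 3), replace=False)
        dr = rng.choice(n_drug, size=rng.integers(1, 3), replace=False)
        reports.append(make_report(
            f"p{i}", tuple(f"D{j}" for j in dis), tuple(f"M{j}" for j in dr),
            age=int(rng.integers(1, 90)), sex=int(rng.integers(1, 3)),
            weight=float(rng.integers(40, 100)), adrs=("S1",)))
    # ensure full vocab coverage
    reports.append(make_report(
        "pall", tuple(f"D{j}" for j in range(n_dis)),
        tuple(f"M{j}" for j in range(n_drug)), adrs=("S1",)))
    vocab = build_vocabulary(reports)
    return build_graph(reports, vocab, FeatureConfig())


def gelu(x):
    return x * 0.5 * (1.0 + erf(x / math.sqrt(2.0)))


def oracle_project(graph, params, config):
    out = {}
    for t in config.node_types:
        x = graph.node_features(t) @ params[f"W_{t}"].data
        h = np.empty_like(x)
        for i in range(x.shape[0]):
            row = x[i]
            h[i] = ((row - row.mean()) / math.sqrt(row.var() + 1e-5)
                    * params[f"ln_gamma_{t}"].data + params[f"ln_beta_{t}"].data)
        out[t] = h
    return out


def oracle_layer(h, graph, params, config, layer):
    dh = config.d_h
    out = {}
    for t in config.node_types:
        n_t = graph.n_nodes(t)
        incoming = []   # (edge_name, src_type, src, tgt)
        for name, (src_t, dst_t) in EDGE_TYPES.items():
            if dst_t != t or name not in config.edge_types:
                continue
            for s, d in graph.edges[name].T:
                incoming.append((name, src_t, int(s), int(d)))
        if not incoming:
            out[t] = h[t].copy()
            continue
        new = h[t].copy()
        for tgt in range(n_t):
            edges = [e for e in incoming if e[3] == tgt]
            if not edges:
                continue
            agg = np.zeros(config.d)
            for head in range(config.h):
                q = (h[t][tgt] @ params[f"Q_{layer}_{t}"].data
                     )[head * dh:(head + 1) * dh]
                logits, msgs = [], []
                for name, src_t, s, _ in edges:
                    k = (h[src_t][s] @ params[f"K_{layer}_{src_t}"].data
                         )[head * dh:(head + 1) * dh]
                    watt = params[f"Watt_{layer}_{name}"].data[head]
                    mu = params[f"mu_{layer}_{name}"].data[head]
                    logits.append((k @ watt @ q) * mu / config.att_denominator)
                    m = (h[src_t][s] @ params[f"M_{layer}_{src_t}"].data
                         )[head * dh:(head + 1) * dh]
                    msgs.append(m @ params[f"Wmsg_{layer}_{name}"].data[head])
                logits = np.array(logits)
                att = np.exp(logits - logits.max())
                att /= att.sum()
                agg[head * dh:(head + 1) * dh] = sum(
                    a * m for a, m in zip(att, msgs))
            upd = gelu(agg @ params[f"A_{layer}_{t}"].data
                       + params[f"Ab_{layer}_{t}"].data)
            new[tgt] = h[t][tgt] + upd
        out[t] = new
    return out


def oracle_encode(graph, params, config):
    h = oracle_project(graph, params, config)
    for l in range(config.L):
        h = oracle_layer(h, graph, params, config, l)
    return h


@pytest.fixture(scope="module")
def setup():
    graph = toy_graph()
    config = HGTConfig(d=8, h=2, L=2)
    dims = {t: graph.node_features(t).shape[1] for t in config.node_types}
    params = init_hgt_params(config, dims, seed=5)
    # randomize mu and LN affine away from their neutral init
    rng = np.random.default_rng(9)
    for k, v in params.items():
        if k.startswith(("mu_", "ln_", "Ab_")):
            v.data = rng.normal(size=v.data.shape)
    return graph, config, params


def test_projection_matches_rowwise_normalization_oracle(setup):
    graph, config, params = setup
    feats = {t: graph.node_features(t) for t in config.node_types}
    h = project_input(feats, params, config)
    ho = oracle_project(graph, params, config)
    for t in config.node_types:
        assert np.abs(h[t].data - ho[t]).max() < 1e-6


def test_projection_zero_row_is_finite():
    graph = toy_graph()
    config = HGTConfig(d=8, h=2, L=1)
    dims = {t: graph.node_features(t).shape[1] for t in config.node_types}
    params = init_hgt_params(config, dims, seed=1)
    feats = {t: np.zeros_like(graph.node_features(t), dtype=float)
             for t in config.node_types}
    h = project_input(feats, params, config)
    for t in config.node_types:
        assert np.isfinite(h[t].data).all()


def test_projection_width_mismatch_names_type(setup):
    graph, config, params = setup
    with pytest.raises(ValueError, match="patient"):
        project_input({"patient": np.zeros((2, 3))}, params, config)


def test_attention_sums_to_one_per_target_and_head(setup):
    graph, config, params = setup
    h = project_input({t: graph.node_features(t) for t in config.node_types},
                      params, config)
    att = compute_attention(h, graph, params, config, layer=0)
    sums = {t: np.zeros((graph.n_nodes(t), config.h))
            for t in config.node_types}
    for name, w in att.items():
        tgt_type = EDGE_TYPES[name][1]
        np.add.at(sums[tgt_type], graph.edges[name][1], w)
    for t, s in sums.items():
        nonzero = s.sum(axis=1) > 0
        assert np.allclose(s[nonzero], 1.0)


def test_attention_uniform_when_projections_are_zero(setup):
    graph, config, _ = setup
    dims = {t: graph.node_features(t).shape[1] for t in config.node_types}
    params = init_hgt_params(config, dims, seed=0)
    for k, v in params.items():
        if k.split("_")[0] in ("K", "Q"):
            v.data[:] = 0.0
    h = project_input({t: graph.node_features(t) for t in config.node_types},
                      params, config)
    att = compute_attention(h, graph, params, config, layer=0)
    indeg = {t: np.zeros(graph.n_nodes(t)) for t in config.node_types}
    for name in att:
        np.add.at(indeg[EDGE_TYPES[name][1]], graph.edges[name][1], 1)
    for name, w in att.items():
        tgt_type = EDGE_TYPES[name][1]
        expected = 1.0 / indeg[tgt_type][graph.edges[name][1]]
        assert np.allclose(w, expected[:, None])


def test_single_incoming_edge_gets_weight_one():
    r = make_report("p0", ("D0",), ("M0",), adrs=("S1",))
    vocab = build_vocabulary([r])
    graph = build_graph([r], vocab, FeatureConfig())
    config = HGTConfig(d=4, h=2, L=1)
    dims = {t: graph.node_features(t).shape[1] for t in config.node_types}
    params = init_hgt_params(config, dims, seed=3)
    h = project_input({t: graph.node_features(t) for t in config.node_types},
                      params, config)
    att = compute_attention(h, graph, params, config, layer=0)
    # the lone disease and drug nodes each have exactly one incoming edge
    assert np.allclose(att["has_disease"], 1.0)
    assert np.allclose(att["takes"], 1.0)
    # the patient's two incoming edges (one per type) share unit mass
    assert np.allclose(att["disease_of"] + att["taken_by"], 1.0)


def test_message_identity_case(setup):
    graph, config, _ = setup
    dims = {t: graph.node_features(t).shape[1] for t in config.node_types}
    params = init_hgt_params(config, dims, seed=0)
    for k, v in params.items():
        if k.startswith("M_"):
            v.data = np.eye(config.d)
        if k.startswith("Wmsg_"):
            v.data = np.stack([np.eye(config.d_h)] * config.h)
    h = project_input({t: graph.node_features(t) for t in config.node_types},
                      params, config)
    msg = compute_message(h, graph, params, config, layer=0)
    for name, m in msg.items():
        src_t = EDGE_TYPES[name][0]
        assert np.abs(m - h[src_t].data[graph.edges[name][0]]).max() < 1e-12


def test_messages_match_dense_oracle(setup):
    graph, config, params = setup
    h = project_input({t: graph.node_features(t) for t in config.node_types},
                      params, config)
    msg = compute_message(h, graph, params, config, layer=0)
    dh = config.d_h
    for name, m in msg.items():
        src_t = EDGE_TYPES[name][0]
        for e, s in enumerate(graph.edges[name][0]):
            expect = np.concatenate([
                (h[src_t].data[s] @ params[f"M_0_{src_t}"].data
                 )[i * dh:(i + 1) * dh] @ params[f"Wmsg_0_{name}"].data[i]
                for i in range(config.h)])
            assert np.abs(m[e] - expect).max() < 1e-6


def test_encode_matches_dense_oracle(setup):
    graph, config, params = setup
    h = encode(graph, params, config)
    ho = oracle_encode(graph, params, config)
    for t in config.node_types:
        assert np.abs(h[t].data - ho[t]).max() < 1e-5


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_encode_matches_oracle_on_random_graphs(seed):
    graph = toy_graph(n_reports=3, seed=seed)
    config = HGTConfig(d=8, h=4, L=2)
    dims = {t: graph.node_features(t).shape[1] for t in config.node_types}
    params = init_hgt_params(config, dims, seed=seed + 50)
    h = encode(graph, params, config)
    ho = oracle_encode(graph, params, config)
    for t in config.node_types:
        assert np.abs(h[t].data - ho[t]).max() < 1e-5


def test_edgeless_graph_keeps_projected_features():
    r = make_report("p0", ("D0",), ("M0",), adrs=("S1",))
    vocab = build_vocabulary([r])
    graph = build_graph([r], vocab, FeatureConfig())
    for k in graph.edges:
        graph.edges[k] = np.empty((2, 0), dtype=np.intp)
    config = HGTConfig(d=4, h=2, L=1)
    dims = {t: graph.node_features(t).shape[1] for t in config.node_types}
    params = init_hgt_params(config, dims, seed=2)
    h1 = project_input({t: graph.node_features(t) for t in config.node_types},
                       params, config)
    h = encode(graph, params, config)
    for t in config.node_types:
        assert np.array_equal(h[t].data, h1[t].data)


def test_permutation_equivariance_over_patients():
    graph = toy_graph(n_reports=5, seed=4)
    config = HGTConfig(d=8, h=2, L=2)
    dims = {t: graph.node_features(t).shape[1] for t in config.node_types}
    params = init_hgt_params(config, dims, seed=11)
    h = encode(graph, params, config)

    perm = np.random.default_rng(0).permutation(graph.n_patients)
    inv = np.argsort(perm)
    g2 = toy_graph(n_reports=5, seed=4)
    g2.patient_ids = [graph.patient_ids[i] for i in perm]
    g2.x_patient = graph.x_patient[perm]
    g2.y = graph.y[perm]
    for name, (src_t, dst_t) in EDGE_TYPES.items():
        e = graph.edges[name].copy()
        if src_t == "patient":
            e[0] = inv[e[0]]
        if dst_t == "patient":
            e[1] = inv[e[1]]
        g2.edges[name] = e
    h2 = encode(g2, params, config)
    assert np.abs(h2["patient"].data - h["patient"].data[perm]).max() < 1e-8


def test_identical_patients_get_identical_rows():
    a = make_report("pa", ("D0",), ("M0",), age=40, sex=1, weight=70.0,
                    adrs=("S1",))
    b = make_report("pb", ("D0",), ("M0",), age=40, sex=1, weight=70.0,
                    adrs=("S1",))
    vocab = build_vocabulary([a, b])
    graph = build_graph([a, b], vocab, FeatureConfig())
    config = HGTConfig(d=8, h=2, L=2)
    dims = {t: graph.node_features(t).shape[1] for t in config.node_types}
    params = init_hgt_params(config, dims, seed=6)
    h = encode(graph, params, config)
    assert np.abs(h["patient"].data[0] - h["patient"].data[1]).max() < 1e-10


def test_homogeneous_reduction_matches_single_relation_attention():
    """With identical per-type projections, shared edge weights and mu=1,
    the heterogeneous layer reduces to a single-relation graph
    transformer layer (checked against the dense oracle, which collapses
    to exactly that computation)."""
    graph = toy_graph(n_reports=4, seed=8)
    config = HGTConfig(d=8, h=2, L=1)
    dims = {t: graph.node_features(t).shape[1] for t in config.node_types}
    params = init_hgt_params(config, dims, seed=13)
    rng = np.random.default_rng(99)
    shared = {n: rng.normal(size=(config.d, config.d)) * 0.2
              for n in ("K", "Q", "M", "A")}
    shared_att = rng.normal(size=(config.h, config.d_h, config.d_h)) * 0.2
    shared_msg = rng.normal(size=(config.h, config.d_h, config.d_h)) * 0.2
    for k, v in params.items():
        head = k.split("_")[0]
        if head in shared:
            v.data = shared[head].copy()
        elif head == "Watt":
            v.data = shared_att.copy()
        elif head == "Wmsg":
            v.data = shared_msg.copy()
        elif head == "mu":
            v.data = np.ones(config.h)
    h = encode(graph, params, config)
    ho = oracle_encode(graph, params, config)
    for t in config.node_types:
        assert np.abs(h[t].data - ho[t]).max() < 1e-6


def test_config_validation():
    with pytest.raises(ValueError):
        HGTConfig(d=10, h=4)
    with pytest.raises(ValueError):
        HGTConfig(L=0)
    with pytest.raises(ValueError):
        HGTConfig(edge_types=("bogus",))


def test_encode_deterministic_checksum(setup):
    graph, config, params = setup
    a = encode(graph, params, config)["patient"].data
    b = encode(graph, params, config)["patient"].data
    assert np.array_equal(a, b)
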
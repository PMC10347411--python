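"""Straight-loop reference implementations used as independent oracles.

Everything here is deliberately unvectorized and dependency-free so it cannot
share a bug with the implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np


def pearson_matrix_bruteforce(X: np.ndarray) -> np.ndarray:
    """Textbook covariance / SD-ratio Pearson matrix, entry by entry."""
    T, R = X.shape
    out = np.eye(R)
    for i in range(R):
        for j in range(i + 1, R):
            xi, xj = X[:, i], X[:, j]
            mi, mj = xi.mean(), xj.mean()
            cov = ((xi - mi) * (xj - mj)).sum() / (T - 1)
            si = math.sqrt(((xi - mi) ** 2).sum() / (T - 1))
            sj = math.sqrt(((xj - mj) ** 2).sum() / (T - 1))
            out[i, j] = out[j, i] = cov / (si * sj)
    return out


def metrics_bruteforce(pred, true):
    n = len(pred)
    mae = sum(abs(p - t) for p, t in zip(pred, true)) / n
    rmse = math.sqrt(sum((p - t) ** 2 for p, t in zip(pred, true)) / n)
    mp = sum(pred) / n
    mt = sum(true) / n
    num = sum((p - mp) * (t - mt) for p, t in zip(pred, true))
    den = math.sqrt(sum((p - mp) ** 2 for p in pred) * sum((t - mt) ** 2 for t in true))
    return mae, rmse, num / den


def transformer_conv_loop(x, edges, edge_feats, conv):
    """Per-vertex, per-head loop evaluation of the attention convolution.

    ``edges`` is a list of directed (src, dst) pairs; messages flow from the
    in-neighbor j (src) to vertex i (dst).
    """
    R, _ = x.shape
    H, d = conv.n_heads, conv.head_dim

    def head_slice(mat, h):
        return mat[:, h * d : (h + 1) * d]

    Wq, bq = conv.w_query.data, conv.b_query.data
    Wk, bk = conv.w_key.data, conv.b_key.data
    Wv, bv = conv.w_value.data, conv.b_value.data
    we, be = conv.w_edge.data, conv.b_edge.data
    Wr, br = conv.w_root.data, conv.b_root.data

    in_neighbors = {i: [] for i in range(R)}
    for (src, dst), ef in zip(edges, edge_feats):
        in_neighbors[dst].append((src, ef))

    out = np.zeros((R, H * d))
    for i in range(R):
        for h in range(H):
            q_i = x[i] @ head_slice(Wq, h) + bq[h * d : (h + 1) * d]
            neigh = in_neighbors[i]
            if not neigh:
                agg = np.zeros(d)
            else:
                scores = []
                values = []
                for j, ef in neigh:
                    e_emb = ef * we[h * d : (h + 1) * d] + be[h * d : (h + 1) * d]
                    k_ij = x[j] @ head_slice(Wk, h) + bk[h * d : (h + 1) * d]
                    v_ij = x[j] @ head_slice(Wv, h) + bv[h * d : (h + 1) * d]
                    if conv.use_edge_features:
                        k_ij = k_ij + e_emb
                        v_ij = v_ij + e_emb
                    scores.append(float(q_i @ k_ij) / math.sqrt(d))
                    values.append(v_ij)
                m = max(scores)
                ws = [math.exp(s - m) for s in scores]
                z = sum(ws)
                agg = np.zeros(d)
                for w, v in zip(ws, values):
                    agg += (w / z) * v
            out[i, h * d : (h + 1) * d] = agg
        out[i] += x[i] @ Wr + br
    return out


def layer_norm_loop(v, gain, bias, eps=1e-5):
    mu = v.mean()
    var = ((v - mu) ** 2).mean()
    return (v - mu) / math.sqrt(var + eps) * gain + bias


def forward_loop(model, x, edges, edge_feats):
    """Straight-loop forward pass of the whole regressor (inference mode)."""
    h = x.copy()
    ef = edge_feats
    for conv, norm in zip(model.convs, model.norms):
        h = transformer_conv_loop(h, edges, ef, conv)
        h = np.stack(
            [layer_norm_loop(row, norm.gain.data, norm.bias.data, norm.eps) for row in h]
        )
        h = np.where(h > 0, h, model.config.leaky_slope * h)
    pooled = h.mean(axis=0)
    z = pooled @ model.fc1.weight.data + model.fc1.bias.data
    z = np.maximum(z, 0.0)
    z = (z - model.bn.running_mean) / np.sqrt(model.bn.running_var + model.bn.eps)
    z = z * model.bn.gain.data + model.bn.bias.data
    out = (z @ model.fc2.weight.data + model.fc2.bias.data).item()
    return out * model.out_scale + model.out_loc
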
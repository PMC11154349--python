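"""Independent brute-force reference implementations used by the tests.

Everything here is written with explicit Python loops (no batched linear
algebra) so it shares no code path with the package implementation.
"""

import math

import numpy as np


def attention_bruteforce(x, w_q, w_k, w_v, w_out, n_heads):
    """Loop-based multi-head self-attention reconstruction over time steps."""
    n, m = x.shape
    d_model = w_q.shape[1]
    dh = d_model // n_heads
    q = np.array([[sum(x[t, c] * w_q[c, d] for c in range(m))
                   for d in range(d_model)] for t in range(n)])
    k = np.array([[sum(x[t, c] * w_k[c, d] for c in range(m))
                   for d in range(d_model)] for t in range(n)])
    v = np.array([[sum(x[t, c] * w_v[c, d] for c in range(m))
                   for d in range(d_model)] for t in range(n)])
    merged = np.zeros((n, d_model))
    scores = np.zeros((n_heads, n, n))
    for h in range(n_heads):
        sl = slice(h * dh, (h + 1) * dh)
        for i in range(n):
            logits = []
            for j in range(n):
                dot = sum(q[i, sl][a] * k[j, sl][a] for a in range(dh))
                logits.append(dot / math.sqrt(d_model))
            mx = max(logits)
            exps = [math.exp(l - mx) for l in logits]
            z = sum(exps)
            for j in range(n):
                scores[h, i, j] = exps[j] / z
            for a in range(dh):
                merged[i, h * dh + a] = sum(scores[h, i, j] * v[j, sl][a]
                                            for j in range(n))
    recon = np.array([[sum(merged[t, d] * w_out[d, c] for d in range(d_model))
                       for c in range(m)] for t in range(n)])
    return recon, scores


def normalized_adj_loops(weights):
    m = len(weights)
    a = [[weights[i][j] + (1.0 if i == j else 0.0) for j in range(m)]
         for i in range(m)]
    deg = [sum(a[i][j] for j in range(m)) for i in range(m)]
    return np.array([[a[i][j] / math.sqrt(deg[i]) / math.sqrt(deg[j])
                      for j in range(m)] for i in range(m)])


def diffusion_loops(feats, weights, theta):
    """Neighbor-sum message passing: A_hat @ feats @ theta, all loops."""
    a_hat = normalized_adj_loops(weights)
    m, f = feats.shape
    fo = theta.shape[1]
    mixed = [[sum(a_hat[i][j] * feats[j][c] for j in range(m))
              for c in range(f)] for i in range(m)]
    return np.array([[sum(mixed[i][c] * theta[c][o] for c in range(f))
                      for o in range(fo)] for i in range(m)])


def dynamic_adjacency_loops(de1, de2, alpha):
    m, f = de1.shape
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            s = sum(de1[i][a] * de2[j][a] - de2[i][a] * de1[j][a]
                    for a in range(f))
            out[i, j] = max(math.tanh(alpha * s), 0.0)
    return out


def topk_rows_loops(mat, k):
    out = np.zeros_like(mat)
    for i, row in enumerate(mat):
        order = sorted(range(len(row)), key=lambda j: (-row[j], j))
        for j in order[:k]:
            if row[j] != 0.0:
                out[i, j] = row[j]
    return out


def tgcn_cell_loops(feats, hidden, adjacency, w_u, b_u, w_r, b_r, w_c, b_c):
    """Pencil-and-paper GRU-with-graph-convolution step."""
    m, f = feats.shape
    dh = hidden.shape[1]
    a_hat = normalized_adj_loops(adjacency)

    def gc(zmat, w, b):
        fin = zmat.shape[1]
        mixed = [[sum(a_hat[i][j] * zmat[j][c] for j in range(m))
                  for c in range(fin)] for i in range(m)]
        return np.array([[sum(mixed[i][c] * w[c][o] for c in range(fin)) + b[o]
                          for o in range(dh)] for i in range(m)])

    z = np.concatenate([feats, hidden], axis=1)
    u = 1.0 / (1.0 + np.exp(-gc(z, w_u, b_u)))
    r = 1.0 / (1.0 + np.exp(-gc(z, w_r, b_r)))
    zc = np.concatenate([feats, r * hidden], axis=1)
    c = np.tanh(gc(zc, w_c, b_c))
    h = u * hidden + (1.0 - u) * c
    return h, u, r, c


def auroc_pairwise(scores, labels):
    """O(n^2) concordance count; ties count one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def weighted_f1_tally(pred, true):
    """Per-class tally F1 averaged with support weights."""
    classes = sorted(set(true))
    total = len(true)
    out = 0.0
    for c in classes:
        tp = sum(1 for p, t in zip(pred, true) if p == c and t == c)
        fp = sum(1 for p, t in zip(pred, true) if p == c and t != c)
        fn = sum(1 for p, t in zip(pred, true) if p != c and t == c)
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        support = sum(1 for t in true if t == c)
        out += f1 * support / total
    return out


def confusion_tally(pred, true, classes):
    k = len(classes)
    mat = np.zeros((k, k))
    for t, p in zip(true, pred):
        mat[classes.index(t), classes.index(p)] += 1
    for i in range(k):
        s = mat[i].sum()
        if s > 0:
            mat[i] /= s
    return mat
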
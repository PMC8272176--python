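"""Independent brute-force oracles: explicit scalar loops, no vectorisation.

These deliberately share no code with the package; they re-derive each
operation from its definition so the tests are a genuine cross-check.
"""

import math

import numpy as np


def sigmoid_scalar(x):
    return 1.0 / (1.0 + math.exp(-x))


def squeeze_loops(fm):
    C, H, W = fm.shape
    z = np.zeros(C)
    for n in range(C):
        acc = 0.0
        for i in range(H):
            for j in range(W):
                acc += fm[n, i, j]
        z[n] = acc / (H * W)
    return z


def excite_loops(z, w1, b1, w2, b2):
    hidden = []
    for i in range(w1.shape[0]):
        acc = b1[i]
        for j in range(len(z)):
            acc += w1[i, j] * z[j]
        hidden.append(max(acc, 0.0))
    s = []
    for i in range(w2.shape[0]):
        acc = b2[i]
        for j in range(len(hidden)):
            acc += w2[i, j] * hidden[j]
        s.append(sigmoid_scalar(acc))
    return np.array(s)


def scale_loops(fm, s):
    C, H, W = fm.shape
    out = np.zeros_like(fm, dtype=float)
    for n in range(C):
        for i in range(H):
            for j in range(W):
                out[n, i, j] = s[n] * fm[n, i, j]
    return out


def attention_gate_loops(skip, gate, wx, bx, wg, bg, psi, bpsi):
    Cs, H, W = skip.shape
    Cg = gate.shape[0]
    F = wx.shape[0]
    alpha = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            logit = bpsi
            for f in range(F):
                acc = bx[f] + bg[f]
                for c in range(Cs):
                    acc += wx[f, c] * skip[c, i, j]
                for c in range(Cg):
                    acc += wg[f, c] * gate[c, i, j]
                logit += psi[f] * max(acc, 0.0)
            alpha[i, j] = sigmoid_scalar(logit)
    out = np.zeros_like(skip, dtype=float)
    for c in range(Cs):
        for i in range(H):
            for j in range(W):
                out[c, i, j] = alpha[i, j] * skip[c, i, j]
    return out, alpha


def conv2d_loops(x, w, b):
    """Same-padded cross-correlation; x (Cin,H,W), w (Cout,Cin,k,k)."""
    Cout, Cin, k, _ = w.shape
    H, W = x.shape[1:]
    pad = k // 2
    out = np.zeros((Cout, H, W))
    for co in range(Cout):
        for i in range(H):
            for j in range(W):
                acc = b[co] if b is not None else 0.0
                for ci in range(Cin):
                    for di in range(k):
                        for dj in range(k):
                            ii, jj = i + di - pad, j + dj - pad
                            if 0 <= ii < H and 0 <= jj < W:
                                acc += w[co, ci, di, dj] * x[ci, ii, jj]
                out[co, i, j] = acc
    return out


def conv_transpose_loops(x, w, b, stride=2):
    """Scatter-add transposed convolution; x (Cin,H,W), w (Cin,Cout,s,s)."""
    Cin, H, W = x.shape
    Cout = w.shape[1]
    out = np.zeros((Cout, H * stride, W * stride))
    for ci in range(Cin):
        for i in range(H):
            for j in range(W):
                for di in range(stride):
                    for dj in range(stride):
                        for co in range(Cout):
                            out[co, i * stride + di, j * stride + dj] += (
                                x[ci, i, j] * w[ci, co, di, dj]
                            )
    if b is not None:
        for co in range(Cout):
            out[co] += b[co]
    return out


def bce_loops(pred, mask, eps=1e-7):
    total, n = 0.0, 0
    for p, y in zip(np.ravel(pred), np.ravel(mask)):
        p = min(max(p, eps), 1.0 - eps)
        total += -(y * math.log(p) + (1 - y) * math.log(1 - p))
        n += 1
    return total / n


def confusion_loops(pred, true):
    tp = tn = fp = fn = 0
    for p, t in zip(np.ravel(pred), np.ravel(true)):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return tp, tn, fp, fn


def mse_loops(a, b):
    total, n = 0.0, 0
    for x, y in zip(np.ravel(a), np.ravel(b)):
        total += (x - y) ** 2
        n += 1
    return total / n


def welch_loops(a, b):
    """Welch t statistic and two-sided p via the t-distribution survival fn."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, p
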
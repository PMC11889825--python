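"""Independent brute-force oracles: dense loops and direct definitions only.

These deliberately avoid the package's vectorized implementations so they can
serve as a second, independent route for every score and metric they check.
"""

import math

import numpy as np


def transe_oracle(h, r, t):
    return -math.sqrt(sum((h[i] + r[i] - t[i]) ** 2 for i in range(len(h))))


def transr_oracle(M, h, r, t):
    d = len(r)
    hp = [sum(M[i][j] * h[j] for j in range(len(h))) for i in range(d)]
    tp = [sum(M[i][j] * t[j] for j in range(len(t))) for i in range(d)]
    return -math.sqrt(sum((hp[i] + r[i] - tp[i]) ** 2 for i in range(d)))


def distmult_oracle(h, r, t):
    return sum(h[i] * r[i] * t[i] for i in range(len(h)))


def complex_oracle(h, r, t):
    d = len(h) // 2
    total = 0.0
    for i in range(d):
        hc = complex(h[i], h[d + i])
        rc = complex(r[i], r[d + i])
        tc = complex(t[i], t[d + i])
        total += (hc * rc * tc.conjugate()).real
    return total


def hole_oracle(h, r, t):
    d = len(h)
    corr = [sum(h[i] * t[(i + k) % d] for i in range(d)) for k in range(d)]
    return sum(r[k] * corr[k] for k in range(d))


SCORE_ORACLES = {
    "transe": transe_oracle,
    "distmult": distmult_oracle,
    "complex": complex_oracle,
    "hole": hole_oracle,
}


def confusion_metrics(y_true, y_pred):
    tp = sum(t == 1 and p == 1 for t, p in zip(y_true, y_pred))
    fp = sum(t == 0 and p == 1 for t, p in zip(y_true, y_pred))
    fn = sum(t == 1 and p == 0 for t, p in zip(y_true, y_pred))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def weighted_f1_oracle(y_true, y_pred):
    total = 0.0
    for cls in set(y_true):
        yt = [1 if y == cls else 0 for y in y_true]
        yp = [1 if y == cls else 0 for y in y_pred]
        _, _, f1 = confusion_metrics(yt, yp)
        total += yt.count(1) / len(y_true) * f1
    return total


def silhouette_oracle(X, labels):
    X = np.asarray(X, float)
    n = len(X)
    vals = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in same])
        b = min(
            np.mean([np.linalg.norm(X[i] - X[j])
                     for j in range(n) if labels[j] == other])
            for other in set(labels) if other != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def calinski_harabasz_oracle(X, labels):
    X = np.asarray(X, float)
    n, k = len(X), len(set(labels))
    overall = X.mean(axis=0)
    bg, wg = 0.0, 0.0
    for cls in set(labels):
        pts = X[[i for i in range(n) if labels[i] == cls]]
        c = pts.mean(axis=0)
        bg += len(pts) * np.sum((c - overall) ** 2)
        wg += np.sum((pts - c) ** 2)
    return (bg / (k - 1)) / (wg / (n - k))


def davies_bouldin_oracle(X, labels):
    X = np.asarray(X, float)
    classes = sorted(set(labels))
    cents, spreads = [], []
    for cls in classes:
        pts = X[[i for i in range(len(X)) if labels[i] == cls]]
        c = pts.mean(axis=0)
        cents.append(c)
        spreads.append(np.mean([np.linalg.norm(p - c) for p in pts]))
    k = len(classes)
    total = 0.0
    for i in range(k):
        total += max(
            (spreads[i] + spreads[j]) / np.linalg.norm(cents[i] - cents[j])
            for j in range(k) if j != i
        )
    return total / k
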
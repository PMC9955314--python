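"""Independent brute-force oracles the test suite checks the package against.

These deliberately share no code with the implementation: plain nested
loops, no vectorization, no shared helpers.
"""

import numpy as np


def brute_relieff_k1(X, y, bounds):
    """Single-nearest-hit/miss Relief weights by exhaustive nested loops."""
    n, p = X.shape
    span = bounds[:, 1] - bounds[:, 0]
    W = np.zeros(p)
    for i in range(n):
        best_hit, best_miss = None, None
        d_hit, d_miss = np.inf, np.inf
        for j in range(n):
            if j == i:
                continue
            d = 0.0
            for f in range(p):
                d += abs(X[i, f] - X[j, f]) / span[f]
            if y[j] == y[i]:
                if d < d_hit:
                    d_hit, best_hit = d, j
            else:
                if d < d_miss:
                    d_miss, best_miss = d, j
        for f in range(p):
            W[f] += abs(X[i, f] - X[best_miss, f]) / span[f] / n
            W[f] -= abs(X[i, f] - X[best_hit, f]) / span[f] / n
    return W


def count_confusion(pred, truth):
    """Per-sample confusion counting with explicit conditionals."""
    tp = tn = fp = fn = 0
    for a, b in zip(pred, truth):
        if b == 1 and a == 1:
            tp += 1
        elif b == 0 and a == 0:
            tn += 1
        elif b == 0 and a == 1:
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn
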
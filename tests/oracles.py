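"""Independent naive-loop oracle implementations used only by the tests.

These deliberately avoid numpy vectorization and the package's own code
paths: plain Python loops and exhaustive enumeration, slow but obviously
correct on small inputs.
"""

from __future__ import annotations

import math


def rms_loop(x):
    return math.sqrt(sum(v * v for v in x) / len(x))


def mav_loop(x):
    return sum(abs(v) for v in x) / len(x)


def zc_loop(x, eps):
    """Sign-change zero crossings with amplitude threshold eps."""
    count = 0
    for n in range(len(x) - 1):
        if x[n] * x[n + 1] < 0 and abs(x[n] - x[n + 1]) >= eps:
            count += 1
    return count


def zc_literal_loop(x, eps):
    """The near-zero-product counting rule, taken at face value."""
    count = 0
    for n in range(len(x) - 1):
        if abs(x[n] * x[n + 1]) < eps:
            count += 1
    return count


def wl_loop(x):
    return sum(abs(x[n + 1] - x[n]) for n in range(len(x) - 1))


def ssc_loop(x):
    count = 0
    for n in range(1, len(x) - 1):
        if (x[n] - x[n - 1]) * (x[n + 1] - x[n]) < 0:
            count += 1
    return count


def downsample_loop(x, M):
    out = []
    for k in range(len(x) // M):
        block = x[k * M:(k + 1) * M]
        out.append(sum(block) / M)
    return out


def accuracy_loop(preds, labels):
    correct = sum(1 for p, l in zip(preds, labels) if p == l)
    return 100.0 * correct / len(labels)


def rmse_loop(y, y_hat):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(y, y_hat)) / len(y))


def dtw_bruteforce(a, b):
    """Minimum alignment cost over ALL monotone warping paths.

    Exhaustive depth-first enumeration with steps (1,0), (0,1), (1,1);
    exponential, so only usable for sequences of length <= ~8.
    """
    n, m = len(a), len(b)

    def dist(i, j):
        ai, bj = a[i], b[j]
        try:
            return abs(ai - bj)
        except TypeError:
            return math.sqrt(sum((u - v) ** 2 for u, v in zip(ai, bj)))

    best = [math.inf]

    def walk(i, j, cost):
        cost += dist(i, j)
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, cost)
        if i + 1 < n:
            walk(i + 1, j, cost)
        if j + 1 < m:
            walk(i, j + 1, cost)

    walk(0, 0, 0.0)
    return best[0]


def window_count_loop(n, L, S):
    """Count complete windows by explicit enumeration of start indices."""
    count = 0
    start = 0
    while start + L <= n:
        count += 1
        start += S
    return count
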
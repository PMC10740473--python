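"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive (double loops, exhaustive search) and
shares no code with the package, so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np


def reflect_index(i: int, n: int) -> int:
    """Half-sample symmetric reflection of an out-of-range index."""
    while i < 0 or i >= n:
        if i < 0:
            i = -i - 1
        if i >= n:
            i = 2 * n - 1 - i
    return i


def conv2d_reflect(field: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct double-loop 2-D convolution with reflect padding."""
    r = kernel.shape[0] // 2
    h, w = field.shape
    out = np.zeros_like(field, dtype=np.float64)
    for y in range(h):
        for x in range(w):
            acc = 0.0
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    acc += kernel[r + dy, r + dx] * \
                        field[reflect_index(y + dy, h), reflect_index(x + dx, w)]
            out[y, x] = acc
    return out


def gaussian_kernel_direct(radius: int, sigma: float) -> np.ndarray:
    """Independent evaluation of the normalized 2-D Gaussian grid."""
    size = 2 * radius + 1
    k = np.empty((size, size))
    for u in range(-radius, radius + 1):
        for v in range(-radius, radius + 1):
            k[u + radius, v + radius] = np.exp(-(u * u + v * v) / (2 * sigma * sigma))
    return k / k.sum()


def pairwise_auc(scores, labels) -> float:
    """ROC-AUC over all positive-negative pairs, ties credited one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def _equal_mass_bins(n: int, b: int) -> list[np.ndarray]:
    return np.array_split(np.arange(n), b)


def sweep_oracle(scores, labels) -> tuple[float, int]:
    """Exhaustive all-b evaluation of the monotonic-sweep estimator.

    For every candidate bin count b = 1..n, form equal-mass bins over the
    stably score-sorted sample and test the all-prefixes monotonicity
    condition directly; report the calibration error at the largest passing b.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = len(scores)
    order = np.argsort(scores, kind="stable")
    s, y = scores[order], labels[order]

    def freqs(b):
        return [y[idx].mean() for idx in _equal_mass_bins(n, b)]

    def monotone(b):
        f = freqs(b)
        return all(f[i] <= f[i + 1] for i in range(len(f) - 1))

    b_star = max(b for b in range(1, n + 1)
                 if all(monotone(bp) for bp in range(1, b + 1)))
    value = 0.0
    for idx in _equal_mass_bins(n, b_star):
        value += len(idx) / n * abs(s[idx].mean() - y[idx].mean())
    return value, b_star


def fixed_bin_ece_oracle(scores, labels, n_bins: int) -> float:
    """Direct equal-width ECE: loop over bins, last bin right-closed."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = len(scores)
    total = 0.0
    for k in range(n_bins):
        lo, hi = k / n_bins, (k + 1) / n_bins
        if k == n_bins - 1:
            sel = (scores >= lo) & (scores <= hi)
        else:
            sel = (scores >= lo) & (scores < hi)
        if sel.sum() == 0:
            continue
        total += sel.sum() / n * abs(scores[sel].mean() - labels[sel].mean())
    return total
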
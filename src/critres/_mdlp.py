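"""Fayyad-Irani recursive entropy discretization with MDL stopping.

Used to define information gain for continuous descriptors against a
binary class: a cut point is accepted only when the class-entropy gain
exceeds the minimum-description-length cost of encoding the partition,
and the procedure recurses on both sides.  A descriptor for which no cut
is accepted carries zero information gain.
"""

from __future__ import annotations

import math

import numpy as np


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _class_counts(y_codes: np.ndarray, n_classes: int) -> np.ndarray:
    return np.bincount(y_codes, minlength=n_classes)


def _best_cut(x: np.ndarray, y: np.ndarray, n_classes: int):
    """Best entropy-minimizing boundary cut on sorted data, or None.

    Returns (cut_value, split_index, gain_accepted) where split_index is
    the count of samples on the left side.
    """
    n = len(x)
    if n < 2:
        return None
    total_counts = _class_counts(y, n_classes)
    ent_s = _entropy(total_counts)
    k = int((total_counts > 0).sum())
    if k < 2:
        return None

    # candidate cuts: midpoints between adjacent distinct values
    left = np.zeros(n_classes, dtype=int)
    best = None
    for i in range(n - 1):
        left[y[i]] += 1
        if x[i + 1] == x[i]:
            continue
        right = total_counts - left
        e1, e2 = _entropy(left), _entropy(right)
        n1 = i + 1
        cond = (n1 / n) * e1 + ((n - n1) / n) * e2
        if best is None or cond < best[0]:
            best = (cond, (x[i] + x[i + 1]) / 2.0, n1, e1, e2,
                    int((left > 0).sum()), int((right > 0).sum()))
    if best is None:
        return None

    cond, cut, n1, e1, e2, k1, k2 = best
    gain = ent_s - cond
    delta = math.log2(3**k - 2) - (k * ent_s - k1 * e1 - k2 * e2)
    threshold = (math.log2(n - 1) + delta) / n
    if gain <= threshold:
        return None
    return cut, n1


def mdlp_cut_points(x, y) -> list[float]:
    """Accepted cut points (ascending) for feature *x* against class *y*."""
    x = np.asarray(x, dtype=float)
    codes, _ = _encode(y)
    n_classes = codes.max() + 1 if len(codes) else 0
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], codes[order]
    cuts: list[float] = []
    _recurse(xs, ys, n_classes, cuts)
    return sorted(cuts)


def _recurse(xs, ys, n_classes, cuts):
    res = _best_cut(xs, ys, n_classes)
    if res is None:
        return
    cut, n1 = res
    cuts.append(cut)
    _recurse(xs[:n1], ys[:n1], n_classes, cuts)
    _recurse(xs[n1:], ys[n1:], n_classes, cuts)


def _encode(y):
    y = np.asarray(y)
    classes, codes = np.unique(y, return_inverse=True)
    return codes.astype(int), classes


def information_gain(x, y) -> float:
    """Class-entropy reduction of the MDLP discretization of *x*.

    Zero when MDLP accepts no cut (a single bin carries no information).
    """
    cuts = mdlp_cut_points(x, y)
    if not cuts:
        return 0.0
    x = np.asarray(x, dtype=float)
    codes, classes = _encode(y)
    n_classes = len(classes)
    bins = np.digitize(x, cuts)
    total = _entropy(_class_counts(codes, n_classes))
    cond = 0.0
    n = len(x)
    for b in np.unique(bins):
        mask = bins == b
        cond += (mask.sum() / n) * _entropy(_class_counts(codes[mask], n_classes))
    return total - cond
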
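"""Independent brute-force reference implementations used only by tests.

Deliberately written with explicit Python loops and no code shared with
the package, so they can serve as oracles for the vectorised versions.
"""

from __future__ import annotations

import math
from fractions import Fraction

GRID = 32


def brute_force_features(window, affected_side="right", mirror=True):
    """The ten features of a window, computed with explicit loops.

    Returns a list in the package's fixed feature order.
    """
    frames = []
    for frame in window:
        rows = [[float(v) for v in row] for row in frame]
        if mirror and affected_side == "left":
            rows = [list(reversed(row)) for row in rows]
        frames.append(rows)

    total_cells = 0
    cell_sum = 0.0
    max_sv = -math.inf
    ml_cop_series, ap_cop_series = [], []
    ml_ratio_series, ap_ratio_series = [], []

    for rows in frames:
        frame_total = 0.0
        peak = 0.0
        for i in range(GRID):
            for j in range(GRID):
                v = rows[i][j]
                cell_sum += v
                total_cells += 1
                if v > max_sv:
                    max_sv = v
                if v > peak:
                    peak = v
                frame_total += v
        if frame_total <= 0:
            continue  # zero frames excluded from COP/ratio series

        ml_num = ap_num = 0.0
        left = right = ant = post = 0.0
        for i in range(GRID):
            for j in range(GRID):
                v = rows[i][j]
                ml_num += j * v
                ap_num += i * v
                if j < GRID // 2:
                    left += v
                else:
                    right += v
                if i < GRID // 2:
                    ant += v
                else:
                    post += v
        ml_cop_series.append(ml_num / frame_total)
        ap_cop_series.append(ap_num / frame_total)
        eps = 1e-9 * peak
        ml_ratio_series.append(max(left, eps) / max(right, eps))
        ap_ratio_series.append(max(ant, eps) / max(post, eps))

    def mean(xs):
        return sum(xs) / len(xs)

    def pop_sd(xs):
        mu = mean(xs)
        return math.sqrt(sum((x - mu) ** 2 for x in xs) / len(xs))

    return [
        cell_sum / total_cells,
        max_sv,
        mean(ml_cop_series),
        pop_sd(ml_cop_series),
        mean(ap_cop_series),
        pop_sd(ap_cop_series),
        mean(ml_ratio_series),
        pop_sd(ml_ratio_series),
        mean(ap_ratio_series),
        pop_sd(ap_ratio_series),
    ]


def counting_metrics(cm, k):
    """Precision/recall/F1 for class index ``k`` by per-example counting.

    Expands the confusion matrix into (actual, predicted) pairs and
    counts TP/FP/FN one example at a time; exact rational arithmetic.
    """
    pairs = []
    for a, row in enumerate(cm):
        for p, count in enumerate(row):
            pairs.extend([(a, p)] * int(count))
    tp = sum(1 for a, p in pairs if a == k and p == k)
    fp = sum(1 for a, p in pairs if a != k and p == k)
    fn = sum(1 for a, p in pairs if a == k and p != k)
    precision = Fraction(tp, tp + fp) if tp + fp else Fraction(0)
    recall = Fraction(tp, tp + fn) if tp + fn else Fraction(0)
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else Fraction(0)
    )
    return precision, recall, f1
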
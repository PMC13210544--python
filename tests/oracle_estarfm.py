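"""Naive, loop-based reference implementation of the fusion predictor.

Evaluates the weighted-sum prediction
F(x0,t2) = F(x0,t1) + sum_i W_i V [C(xi,t2) − C(xi,t1)] directly, pixel by
pixel, with explicit Python loops and no shortcuts. Used as the
independent oracle that the fast kernel must reproduce.
"""

import math

import numpy as np


def naive_predict(
    fine1: np.ndarray,
    coarse1: np.ndarray,
    coarse2: np.ndarray,
    window_half_size: int,
    n_classes: int,
    min_similar: int,
    regression_min_points: int,
    min_correlation: float = 0.3,
) -> np.ndarray:
    nr, nc = fine1.shape
    h = window_half_size
    out = np.full((nr, nc), np.nan)
    for i in range(nr):
        for j in range(nc):
            fc = fine1[i, j]
            if math.isnan(fc):
                continue
            r0, r1 = max(0, i - h), min(nr, i + h + 1)
            c0, c1 = max(0, j - h), min(nc, j + h + 1)

            window_vals = []
            for r in range(r0, r1):
                for c in range(c0, c1):
                    if not math.isnan(fine1[r, c]):
                        window_vals.append(fine1[r, c])
            mean = sum(window_vals) / len(window_vals)
            var = sum(v * v for v in window_vals) / len(window_vals) - mean * mean
            sigma = math.sqrt(var) if var > 0 else 0.0
            threshold = 2.0 * sigma / n_classes

            similar = []
            for r in range(r0, r1):
                for c in range(c0, c1):
                    v = fine1[r, c]
                    if (
                        math.isnan(v)
                        or math.isnan(coarse1[r, c])
                        or math.isnan(coarse2[r, c])
                    ):
                        continue
                    if abs(v - fc) <= threshold or (r == i and c == j):
                        similar.append((r, c))

            if len(similar) < min_similar:
                if not (math.isnan(coarse1[i, j]) or math.isnan(coarse2[i, j])):
                    pred = fc + (coarse2[i, j] - coarse1[i, j])
                else:
                    pred = fc
                out[i, j] = min(1.0, max(-1.0, pred))
                continue

            # conversion coefficient: least-squares slope of fine on coarse
            n = len(similar)
            fsum = sum(fine1[r, c] for r, c in similar)
            csum = sum(coarse1[r, c] for r, c in similar)
            mf, mc = fsum / n, csum / n
            s_cc = sum((coarse1[r, c] - mc) ** 2 for r, c in similar)
            s_ff = sum((fine1[r, c] - mf) ** 2 for r, c in similar)
            s_cf = sum(
                (coarse1[r, c] - mc) * (fine1[r, c] - mf) for r, c in similar
            )
            v_coef = 1.0
            if n >= regression_min_points and s_cc / n >= 1e-8:
                degenerate = False
                if s_ff > 0:
                    corr = abs(s_cf) / math.sqrt(s_cc * s_ff)
                    if corr < min_correlation:
                        degenerate = True
                if not degenerate:
                    slope = s_cf / s_cc
                    if 0.0 < abs(slope) <= 5.0:
                        v_coef = slope

            weights = []
            for r, c in similar:
                d = 1.0 + math.hypot(r - i, c - j) / h
                s = 1.0 + abs(fine1[r, c] - coarse1[r, c])
                weights.append(1.0 / (d * s))
            wsum = sum(weights)
            acc = sum(
                w * (coarse2[r, c] - coarse1[r, c])
                for w, (r, c) in zip(weights, similar)
            )
            pred = fc + v_coef * acc / wsum
            out[i, j] = min(1.0, max(-1.0, pred))
    return out
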
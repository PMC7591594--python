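"""Independent brute-force oracles used by the tests.

Deliberately simple O(n^2)-ish implementations kept separate from the
package's own algorithms so that agreement between the two routes is
meaningful.
"""

from __future__ import annotations

import numpy as np


def extrema_oracle(x: np.ndarray, min_sep: float) -> list[tuple[int, bool]]:
    """Alternating landmarks by exhaustive scan + iterative weakest-pair
    pruning, re-collapsing same-type neighbours each round."""
    marks = []
    n = len(x)
    i = 1
    while i < n - 1:
        j = i
        while j < n - 1 and x[j + 1] == x[j]:
            j += 1
        if j < n - 1:
            if x[i] > x[i - 1] and x[i] > x[j + 1]:
                marks.append((i, True))
            elif x[i] < x[i - 1] and x[i] < x[j + 1]:
                marks.append((i, False))
        i = j + 1

    def collapse(seq):
        out = []
        for idx, is_peak in seq:
            if out and out[-1][1] == is_peak:
                prev = out[-1][0]
                if (x[idx] > x[prev]) if is_peak else (x[idx] < x[prev]):
                    out[-1] = (idx, is_peak)
            else:
                out.append((idx, is_peak))
        return out

    marks = collapse(marks)
    while len(marks) >= 2:
        diffs = [abs(x[marks[k + 1][0]] - x[marks[k][0]])
                 for k in range(len(marks) - 1)]
        k = int(np.argmin(diffs))
        if diffs[k] >= min_sep:
            break
        del marks[k:k + 2]
        marks = collapse(marks)
    return marks


def windowed_median_oracle(times, values, t, window_s):
    """Sort-based median of values whose times fall in the centred window."""
    sel = [v for tt, v in zip(times, values)
           if t - window_s / 2 <= tt <= t + window_s / 2]
    if not sel:
        return None
    s = sorted(sel)
    m = len(s)
    return s[m // 2] if m % 2 else 0.5 * (s[m // 2 - 1] + s[m // 2])


def percentile_span_oracle(values, lo=5.0, hi=95.0):
    """Linear-interpolation percentile span from explicit order statistics."""
    s = sorted(values)
    n = len(s)

    def pct(p):
        h = (n - 1) * p / 100.0
        lo_i = int(np.floor(h))
        hi_i = min(lo_i + 1, n - 1)
        return s[lo_i] + (h - lo_i) * (s[hi_i] - s[lo_i])

    return pct(hi) - pct(lo)


def merge_oracle(intervals, min_pause):
    """Sort-and-sweep merge of intervals with gaps below min_pause."""
    out = []
    for a, b in sorted(intervals):
        if out and a - out[-1][1] < min_pause:
            out[-1] = (out[-1][0], b)
        else:
            out.append((a, b))
    return out


def classify_oracle(spurts):
    """Pairwise chronogram classification.

    ``spurts``: list of (speaker, start, end).  Returns a set of tuples
    (base, prev_speaker, next_speaker, t_start, t_end) for comparison.
    """
    out = set()
    ordered = sorted(spurts, key=lambda s: (s[1], -(s[2] - s[1])))
    for i, (spk_a, a0, a1) in enumerate(ordered):
        for spk_b, b0, b1 in ordered[i + 1:]:
            if b0 >= a1:
                if b0 > a1:
                    base = "WSS" if spk_b == spk_a else "BSS"
                    out.add((base, spk_a, spk_b, a1, b0))
                break
            if b1 <= a1:
                out.add(("WSO", spk_a, spk_a, b0, b1))
                continue
            out.add(("BSO", spk_a, spk_b, b0, a1))
            break
    return out


def run_length_holds_oracle(t, x, level, margin, min_hold, min_gap):
    """Plateau spans by direct run-length scan at a known level."""
    inside = np.abs(np.asarray(x) - level) <= margin
    runs, start = [], None
    for i, flag in enumerate(inside):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((t[start], t[i - 1]))
            start = None
    if start is not None:
        runs.append((t[start], t[len(t) - 1]))
    merged = []
    for a, b in runs:
        if merged and a - merged[-1][1] < min_gap:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    return [(a, b) for a, b in merged if b - a >= min_hold]


def multinomial_mle_oracle(X, y, n_levels):
    """Maximum-likelihood multinomial logit via generic numerical
    optimization of the hand-written log-likelihood (reference level 0)."""
    from scipy.optimize import minimize

    n, k = X.shape

    def negll(theta):
        B = theta.reshape(n_levels - 1, k)
        eta = np.column_stack([np.zeros(n), X @ B.T])
        logz = np.log(np.sum(np.exp(eta - eta.max(1, keepdims=True)), 1)) \
            + eta.max(1)
        return -(eta[np.arange(n), y] - logz).sum()

    res = minimize(negll, np.zeros((n_levels - 1) * k), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 500})
    return res.x.reshape(n_levels - 1, k), -res.fun
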
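"""Independent brute-force oracles used by the unit and acceptance tests.

Each function re-derives an operation's contract by direct enumeration,
deliberately sharing no code with the implementation it checks.
"""

from __future__ import annotations

import numpy as np


def edr_bruteforce(eda: np.ndarray, t_edr_s: float, a_edr_us: float, step_s: float = 0.5) -> np.ndarray:
    """O(n·w) scan: rise over every trailing window, thresholded."""
    n = len(eda)
    w = int(round(t_edr_s / step_s)) + 1
    out = np.zeros(n)
    for i in range(n):
        lo = max(0, i - w + 1)
        rise = eda[i] - min(eda[lo : i + 1])
        if rise >= a_edr_us - 1e-9:
            out[i] = rise
    return out


def movavg_bruteforce(x: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    """Per-window mean with windows delimited by sample start times."""
    nper = fs * window_s
    nout = int(np.floor(len(x) / nper + 1e-9))
    buckets: list[list[float]] = [[] for _ in range(nout)]
    for i, v in enumerate(x):
        k = int(i / nper)
        if k < nout:
            buckets[k].append(float(v))
    return np.array([float(np.mean(b)) for b in buckets])


def median_interp_bruteforce(x: np.ndarray, mask: np.ndarray, order: int) -> np.ndarray:
    """Naive windowed-median replacement on unflagged neighbours."""
    if order % 2 == 0:
        order += 1
    half = order // 2
    out = x.astype(float).copy()
    good = [i for i in range(len(x)) if not mask[i]]
    for i in range(len(x)):
        if not mask[i]:
            continue
        vals = [
            x[j]
            for j in range(max(0, i - half), min(len(x), i + half + 1))
            if not mask[j]
        ]
        if vals:
            out[i] = float(np.median(vals))
        else:
            j = min(good, key=lambda g: abs(g - i))
            out[i] = x[j]
    return out


def best_subset_selection(
    times: np.ndarray, scores: np.ndarray, n_max: int, min_sep_s: float
) -> float:
    """Max total score over all feasible subsets of at most n_max candidates
    under the pairwise separation constraint (exhaustive enumeration)."""
    from itertools import combinations

    idx = list(range(len(times)))
    best = 0.0
    for k in range(1, n_max + 1):
        for sub in combinations(idx, k):
            if all(
                abs(times[a] - times[b]) >= min_sep_s
                for a, b in combinations(sub, 2)
            ):
                best = max(best, float(sum(scores[list(sub)])))
    return best
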
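"""Independent oracles used by the test suite.

Kept deliberately naive and separate from the package implementation: a
pure-Python Smith-Waterman DP, an exhaustive local-alignment enumeration
(validating the DP itself at tiny lengths), a window brute force for
profile scanning, and a brute-force optimal makespan.
"""

from __future__ import annotations

import itertools


def sw_dp(a: str, b: str, match: int, mismatch: int, gap: int) -> int:
    """Plain-Python local alignment DP with linear gaps (score only)."""
    n, m = len(a), len(b)
    best = 0
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            cur[j] = max(0, prev[j - 1] + s, prev[j] + gap, cur[j - 1] + gap)
            if cur[j] > best:
                best = cur[j]
        prev = cur
    return best


def _global_enum(a: str, b: str, match: int, mismatch: int, gap: int) -> int:
    """Best global alignment score by exhaustive recursion over edit ops."""
    if not a:
        return gap * len(b)
    if not b:
        return gap * len(a)
    sub = (match if a[-1] == b[-1] else mismatch) + _global_enum(
        a[:-1], b[:-1], match, mismatch, gap
    )
    del_a = gap + _global_enum(a[:-1], b, match, mismatch, gap)
    del_b = gap + _global_enum(a, b[:-1], match, mismatch, gap)
    return max(sub, del_a, del_b)


def sw_enum(a: str, b: str, match: int, mismatch: int, gap: int) -> int:
    """Best local score by enumerating every substring pair (lengths <= ~6)."""
    best = 0
    for i1, i2 in itertools.combinations_with_replacement(range(len(a) + 1), 2):
        for j1, j2 in itertools.combinations_with_replacement(range(len(b) + 1), 2):
            if i1 == i2 or j1 == j2:
                continue
            score = _global_enum(a[i1:i2], b[j1:j2], match, mismatch, gap)
            if score > best:
                best = score
    return best


def profile_best_window(query: str, alphabet: str, weights) -> tuple[int, float] | None:
    """Leftmost best ungapped window by explicit offset loop."""
    L = len(weights)
    if len(query) < L:
        return None
    best_o, best_s = None, None
    for o in range(len(query) - L + 1):
        s = sum(weights[i][alphabet.index(query[o + i])] for i in range(L))
        if best_s is None or s > best_s:
            best_o, best_s = o, s
    return best_o, best_s


def optimal_makespan(durations, workers) -> float:
    """Brute-force minimal makespan over all batch-to-worker assignments.

    Batch order within a worker does not affect makespan for independent
    batches with zero dispatch latency, so assignment enumeration suffices.
    """
    best = float("inf")
    for assign in itertools.product(range(workers), repeat=len(durations)):
        loads = [0.0] * workers
        for b, w in enumerate(assign):
            loads[w] += durations[b]
        best = min(best, max(loads))
    return best
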
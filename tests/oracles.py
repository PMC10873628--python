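"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results through a different route than the
implementation: the alignment oracle is a memoized recursion with a greedy
forward reconstruction (the implementation uses iterative suffix tables),
and the classification oracle is a literal restatement of the cutoff rules.
"""

import functools

from curtainkit.ptm_map import AlignmentParams, _scorer


def brute_force_align(a: str, b: str, params: AlignmentParams | None = None):
    """Optimal global affine-gap alignment score and aligned-pair list,
    tie-broken diagonal > up > left reading from the start."""
    params = params or AlignmentParams()
    sub = _scorer(params)
    go, ge = params.gap_open, params.gap_extend
    n, m = len(a), len(b)

    @functools.lru_cache(maxsize=None)
    def best(i: int, j: int, state: int) -> float:
        if i == n and j == m:
            return 0.0
        v = float("-inf")
        if i < n and j < m:
            v = max(v, sub(a[i], b[j]) + best(i + 1, j + 1, 0))
        if i < n:
            v = max(v, (ge if state == 1 else go) + best(i + 1, j, 1))
        if j < m:
            v = max(v, (ge if state == 2 else go) + best(i, j + 1, 2))
        return v

    pairs = []
    i = j = 0
    state = 0
    while i < n or j < m:
        r = best(i, j, state)
        if i < n and j < m and sub(a[i], b[j]) + best(i + 1, j + 1, 0) == r:
            pairs.append((i + 1, j + 1))
            i, j, state = i + 1, j + 1, 0
        elif i < n and (ge if state == 1 else go) + best(i + 1, j, 1) == r:
            i, state = i + 1, 1
        else:
            j, state = j + 1, 2
    score = best(0, 0, 0)
    best.cache_clear()
    return score, pairs


def classify_by_hand(log2_fc: float, neglog10_sig: float,
                     fc_cutoff: float, sig_cutoff: float) -> str:
    """Literal restatement of the four-class volcano rule."""
    sig = neglog10_sig > sig_cutoff
    if log2_fc > fc_cutoff or -log2_fc > fc_cutoff:
        return "S_C" if sig else "NS_C"
    return "S_NC" if sig else "NS_NC"
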
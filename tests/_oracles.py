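"""Independent brute-force oracles used to cross-check the implementation."""

from __future__ import annotations


def gotoh_local_score(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -4.0,
    gap_open: float = -4.0,
    gap_extend: float = -2.0,
) -> float:
    """Optimal local affine-gap alignment score by full dynamic programming.

    A gap of length k costs ``gap_open + k * gap_extend``.  Plain O(nm)
    three-matrix recursion (Smith-Waterman-Gotoh) kept deliberately naive and
    separate from the package's aligner.
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    h_prev = [0.0] * (m + 1)
    e_prev = [neg] * (m + 1)
    f_prev = [neg] * (m + 1)
    first = gap_open + gap_extend
    best = 0.0
    for i in range(1, n + 1):
        h_row = [0.0] * (m + 1)
        e_row = [neg] * (m + 1)
        f_row = [neg] * (m + 1)
        ai = a[i - 1]
        for j in range(1, m + 1):
            e_row[j] = max(h_row[j - 1] + first, e_row[j - 1] + gap_extend)
            f_row[j] = max(h_prev[j] + first, f_prev[j] + gap_extend)
            s = match if ai == b[j - 1] else mismatch
            h_row[j] = max(0.0, h_prev[j - 1] + s, e_row[j], f_row[j])
            if h_row[j] > best:
                best = h_row[j]
        h_prev, e_prev, f_prev = h_row, e_row, f_row
    return best
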
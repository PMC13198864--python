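"""JIT-compiled inner loops for the windowed haploid similarity."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def best_run_sums(match: np.ndarray, terms: np.ndarray) -> np.ndarray:
    """Per row, the term sum over the best contiguous run of matches.

    ``match`` is ``(R, L)`` boolean, ``terms`` an ``(L,)`` float vector of
    per-site contributions (valid wherever the row matches).  The best run
    is the longest contiguous stretch of True; ties go to the larger term
    sum, then to the leftmost start (the scan keeps the earlier run on
    exact ties).
    """
    R, L = match.shape
    out = np.zeros(R, dtype=np.float64)
    for r in range(R):
        best_len = 0
        best_sum = 0.0
        cur_len = 0
        cur_sum = 0.0
        for k in range(L):
            if match[r, k]:
                cur_len += 1
                cur_sum += terms[k]
            else:
                if cur_len > best_len or (cur_len == best_len and cur_sum > best_sum):
                    best_len = cur_len
                    best_sum = cur_sum
                cur_len = 0
                cur_sum = 0.0
        if cur_len > best_len or (cur_len == best_len and cur_sum > best_sum):
            best_sum = cur_sum
        out[r] = best_sum
    return out
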
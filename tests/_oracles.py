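"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations, kept free of the library's optimised
code paths so agreement is meaningful.
"""

import numpy as np


def naive_sad_curve(ref, test):
    """Double-loop SAD rotIDF: one explicit gather per rotation index."""
    ref = np.asarray(ref, dtype=np.int64)
    test = np.asarray(test, dtype=np.int64)
    w = ref.shape[1]
    cols = np.arange(w)
    out = np.empty(w, dtype=np.int64)
    for r in range(w):
        rotated = test[:, (cols + r) % w]
        out[r] = np.abs(ref - rotated).sum()
    return out


def naive_block_mean(arr, fy, fx):
    """Per-block python-loop block average."""
    h, w = arr.shape
    out = np.empty((h // fy, w // fx))
    for i in range(h // fy):
        for j in range(w // fx):
            out[i, j] = arr[i * fy : (i + 1) * fy, j * fx : (j + 1) * fx].mean()
    return out


def last_height_maximum_suffix(heights):
    """Index of the start of the final descent by exhaustive scan.

    The last index i that starts a monotone non-increasing run to the end
    and is either the first point or a strict rise from its predecessor.
    """
    n = len(heights)
    for i in range(n - 1, -1, -1):
        run = all(heights[k] >= heights[k + 1] for k in range(i, n - 1))
        rise = i == 0 or heights[i - 1] < heights[i]
        if run and rise:
            return i
    return 0
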
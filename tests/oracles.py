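"""Independent brute-force oracles shared across test modules.

These deliberately re-derive quantities with the simplest possible
O(n^2) / per-sample algorithms, independent of the library code paths
they check.
"""

import numpy as np


def sampen_bruteforce(x, m, r):
    """Double-loop sample entropy: -ln(A/B) with Chebyshev tolerance r."""
    x = np.asarray(x, float)
    n = x.size
    nt = n - m
    b = a = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    if b == 0:
        return np.nan
    if a == 0:
        return np.inf
    return -np.log(a / b)


def quad_sec_bruteforce(g, grid=(4, 4), dur_s=None) -> float:
    """Per-sample quadrant-walk visit counter over a gaze stream."""
    rows, cols = grid
    w, h = g.screen
    dur_s = dur_s or (g.t_ms[-1] - g.t_ms[0]) / 1000.0
    n_q = 0
    prev = None
    for t, x, y, v in zip(g.t_ms, g.x, g.y, g.valid):
        if not v:
            continue
        qx = min(int(x / w * cols), cols - 1) if x >= 0 else 0
        qy = min(int(y / h * rows), rows - 1) if y >= 0 else 0
        q = qy * cols + qx
        if prev is None or q != prev:
            n_q += 1
        prev = q
    return n_q / dur_s
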
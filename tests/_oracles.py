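"""Independent brute-force reference implementations used only by tests."""

import numpy as np


def lz76_phrases_bruteforce(s: str) -> int:
    """Exhaustive-history LZ76 phrase count by direct substring search.

    A phrase starting at p is extended while it can be reproduced from the
    extended past s[:p+L-1]; the first non-reproducible extension closes the
    phrase.  The trailing (possibly reproducible) remainder counts as one
    phrase.
    """
    n = len(s)
    c = 0
    p = 0
    while p < n:
        L = 1
        while p + L <= n and s[p : p + L] in s[: p + L - 1]:
            L += 1
        c += 1
        p += min(L, n - p)
    return c


def sampen_bruteforce(x, m: int = 2, r_frac: float = 0.2) -> float:
    """Sample entropy by the O(N^2) definition, counting ordered pairs.

    Chebyshev distance, tolerance r_frac x SD, self-matches excluded.
    Returns nan when either count is zero.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    r = r_frac * float(np.std(x))
    nt = n - m  # template starts for both lengths m and m+1
    b = 0
    a = 0
    for i in range(nt):
        for j in range(nt):
            if i == j:
                continue
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    if b == 0 or a == 0:
        return float("nan")
    return float(-np.log(a / b))
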
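"""Independent brute-force pooling oracle used only by the tests.

Deliberately written as plain compensated-summation loops (math.fsum is
exact for float addition) with no shared code path with the package's
pooling module.
"""

import math


def pool_oracle(ys, vs):
    """Return (b_hat, var_b, ci_low, ci_high, q, i2_percent)."""
    ws = [1.0 / v for v in vs]
    sw = math.fsum(ws)
    b = math.fsum(w * y for w, y in zip(ws, ys)) / sw
    var_b = 1.0 / sw
    half = 1.96 * math.sqrt(var_b)
    q = math.fsum(w * (y - b) ** 2 for w, y in zip(ws, ys))
    k = len(ys)
    if k >= 2 and q > 0:
        i2 = max(0.0, (q - (k - 1)) / q) * 100.0
    else:
        i2 = 0.0
    return b, var_b, b - half, b + half, q, i2
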
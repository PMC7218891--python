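"""Independent brute-force LBP reference used to cross-check the
vectorized implementation.

Deliberately naive: explicit per-pixel loops, explicit bilinear
interpolation from the four surrounding integer pixels, explicit circular
bit-transition counting.  Shares only the published conventions with the
implementation under test (neighbor angles, ≥ tie rule, 6-decimal rounding
of interpolated values), not any code.
"""

import math

import numpy as np


def brute_force_riu2(gray: np.ndarray, P: int, R: int) -> np.ndarray:
    """riu2 codes on the interior; -1 on the border of width R."""
    g = np.asarray(gray, dtype=float)
    H, W = g.shape
    out = np.full((H, W), -1, dtype=int)
    for i in range(R, H - R):
        for j in range(R, W - R):
            bits = []
            for p in range(P):
                a = 2.0 * math.pi * p / P
                y = i - R * math.sin(a)
                x = j + R * math.cos(a)
                y0, x0 = math.floor(y), math.floor(x)
                fy, fx = y - y0, x - x0
                if fy < 1e-9 and fx < 1e-9:
                    val = g[y0, x0]
                elif fy > 1 - 1e-9 and fx < 1e-9:
                    val = g[y0 + 1, x0]
                elif fy < 1e-9 and fx > 1 - 1e-9:
                    val = g[y0, x0 + 1]
                else:
                    val = ((1 - fy) * (1 - fx) * g[y0, x0]
                           + (1 - fy) * fx * g[y0, x0 + 1]
                           + fy * (1 - fx) * g[y0 + 1, x0]
                           + fy * fx * g[y0 + 1, x0 + 1])
                    val = round(val, 6)
                bits.append(1 if val >= g[i, j] else 0)
            transitions = sum(bits[p] != bits[(p + 1) % P] for p in range(P))
            out[i, j] = sum(bits) if transitions <= 2 else P + 1
    return out
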